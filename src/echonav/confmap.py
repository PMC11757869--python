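"""Confidence maps of heart-component detectability over the chest grid.

A confidence map assigns to every probe position on an ``n_x x n_y`` grid the
detection confidence ``C`` (in ``[0, 1]``) of a heart component — here the
mitral valve — as seen by an object detector in the ultrasound frames acquired
at that position.  The grid's origin cell sits at the xiphoid process; ``X``
increases caudocranially along the body's vertical axis and ``Y`` laterally.

The synthetic generator emulates the statistical structure of such maps on a
real chest: a single cardiac confidence peak biased toward the lower left of
the chest, periodic rib-shadow attenuation along the vertical axis that turns
the peak's flanks into non-global local maxima, a zero-confidence band where
the sternum and lungs block the acoustic window, per-subject variation of the
peak's position, and per-frame detector noise aggregated by the median.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GridGeometry",
    "ConfidenceMap",
    "MapGenParams",
    "DegenerateMapError",
    "MapValidationError",
    "sample_frames",
    "aggregate_frames",
    "generate_map",
    "generate_cohort",
    "read_map",
    "write_map",
]


class DegenerateMapError(RuntimeError):
    """Raised when a generated map carries no confidence anywhere."""


class MapValidationError(ValueError):
    """Raised when a map file violates the confidence-map invariants."""


@dataclass(frozen=True)
class GridGeometry:
    """Cell counts of the chest grid: ``n_x`` along the body's vertical axis,
    ``n_y`` along the frontal (lateral) axis.  The default 7 x 5 grid has the
    35 probe positions of a full chest sweep."""

    n_x: int = 7
    n_y: int = 5

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.n_x}x{self.n_y}")

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    def contains(self, cell: tuple[int, int]) -> bool:
        x, y = cell
        return 0 <= x < self.n_x and 0 <= y < self.n_y

    def cells(self) -> Iterable[tuple[int, int]]:
        for x in range(self.n_x):
            for y in range(self.n_y):
                yield (x, y)


@dataclass(frozen=True)
class ConfidenceMap:
    """Per-subject grid of detection confidences.

    ``c`` is an ``(n_x, n_y)`` array with every value in ``[0, 1]``;
    ``optimal_cell`` is the unique global argmax and ``c_m`` the confidence
    there.  Ties at the global maximum are forbidden: the optimal solution of
    the search problem must be well defined.
    """

    subject_id: str
    geometry: GridGeometry
    c: np.ndarray
    optimal_cell: tuple[int, int] = field(init=False)
    c_m: float = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.shape != (self.geometry.n_x, self.geometry.n_y):
            raise MapValidationError(
                f"grid shape {c.shape} does not match geometry "
                f"{(self.geometry.n_x, self.geometry.n_y)}"
            )
        if not np.all(np.isfinite(c)):
            raise MapValidationError("confidences must be finite")
        if c.min() < 0.0 or c.max() > 1.0:
            raise MapValidationError("confidences must lie in [0, 1]")
        cmax = c.max()
        if cmax <= 0.0:
            raise DegenerateMapError("map has no positive confidence anywhere")
        if int(np.count_nonzero(c == cmax)) != 1:
            raise MapValidationError("global maximum must be unique")
        object.__setattr__(self, "c", c)
        idx = np.unravel_index(int(np.argmax(c)), c.shape)
        object.__setattr__(self, "optimal_cell", (int(idx[0]), int(idx[1])))
        object.__setattr__(self, "c_m", float(cmax))

    def confidence_at(self, cell: tuple[int, int]) -> float:
        if not self.geometry.contains(cell):
            raise ValueError(f"cell {cell} outside grid")
        return float(self.c[cell])


@dataclass(frozen=True)
class MapGenParams:
    """Parameters of the synthetic chest-map generator.

    The heart's confidence peak is an isotropic squared-exponential surface of
    height ``peak_height`` and decay scale ``peak_width`` (cells) around a
    per-subject centre drawn from ``heart_center_mean`` +/-
    ``heart_center_spread``.  Rows whose ``X`` index is congruent to
    ``rib_phase`` modulo ``rib_period`` are multiplied by ``rib_attenuation``
    (rib acoustic shadows); columns in ``dead_zone_columns`` are forced to
    zero (sternum/lung band).  Each remaining cell's confidence is the median
    of ``frames_per_cell`` simulated detector frames with per-frame noise
    ``frame_noise_spread`` on top of a per-cell offset of scale
    ``noise_spread``.
    """

    geometry: GridGeometry = GridGeometry()
    heart_center_mean: tuple[float, float] = (4.0, 3.0)
    heart_center_spread: tuple[float, float] = (0.8, 0.7)
    peak_height: float = 0.9
    peak_width: float = 1.6
    rib_period: int = 2
    rib_phase: int = 1
    rib_attenuation: float = 0.4
    dead_zone_columns: frozenset[int] = frozenset({0})
    noise_spread: float = 0.02
    frames_per_cell: int = 5
    frame_noise_spread: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rib_period < 2:
            raise ValueError("rib_period must be >= 2")
        if not 0.0 <= self.rib_attenuation <= 1.0:
            raise ValueError("rib_attenuation must lie in [0, 1]")
        if not 0.0 < self.peak_height <= 1.0:
            raise ValueError("peak_height must lie in (0, 1]")
        for s in (*self.heart_center_spread, self.noise_spread, self.frame_noise_spread):
            if s < 0:
                raise ValueError("spreads must be >= 0")
        if self.frames_per_cell < 1:
            raise ValueError("frames_per_cell must be >= 1")
        object.__setattr__(self, "dead_zone_columns", frozenset(self.dead_zone_columns))


def sample_frames(
    true_c: float, k: int, noise: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Simulate ``k`` per-frame detection confidences around a true value.

    Each frame is ``true_c`` plus zero-centred Gaussian noise of scale
    ``noise``, clipped to ``[0, 1]``.  Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("need at least one frame")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = true_c + rng.normal(0.0, 1.0, size=k) * noise
    return np.clip(frames, 0.0, 1.0)


def aggregate_frames(frames: Sequence[float]) -> float:
    """Aggregate per-frame confidences into the cell's confidence ``C``.

    The median is used: for even counts, the midpoint of the two central
    order statistics.
    """
    arr = np.asarray(frames, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty frame sequence")
    return float(np.median(arr))


def _peak_surface(params: MapGenParams, center: tuple[float, float]) -> np.ndarray:
    g = params.geometry
    xs = np.arange(g.n_x, dtype=float)[:, None]
    ys = np.arange(g.n_y, dtype=float)[None, :]
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    return params.peak_height * np.exp(-d2 / (2.0 * params.peak_width**2))


def _bump_ties(c: np.ndarray) -> np.ndarray:
    # Unique-argmax invariant: nudge the lexicographically smallest tied cell
    # upward by the smallest representable increments until it wins alone.
    cmax = c.max()
    tied = np.argwhere(c == cmax)
    if len(tied) <= 1:
        return c
    winner = tuple(int(v) for v in min(map(tuple, tied)))
    bumped = float(cmax)
    while np.count_nonzero(c == c.max()) > 1 or c[winner] != c.max():
        bumped = math.nextafter(bumped, math.inf)
        c[winner] = min(bumped, 1.0)
        if c[winner] == 1.0 and np.count_nonzero(c == 1.0) > 1:
            # everyone else at 1.0 must move down instead
            others = [t for t in map(tuple, np.argwhere(c == 1.0)) if t != winner]
            for t in others:
                c[t] = math.nextafter(c[t], 0.0)
    return c


def generate_map(params: MapGenParams) -> ConfidenceMap:
    """Generate one synthetic subject map; fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    g = params.geometry
    cx = params.heart_center_mean[0] + rng.normal() * params.heart_center_spread[0]
    cy = params.heart_center_mean[1] + rng.normal() * params.heart_center_spread[1]
    # keep the peak on the grid so a subject always has an observable heart
    cx = float(np.clip(cx, 0.0, g.n_x - 1.0))
    cy = float(np.clip(cy, 0.0, g.n_y - 1.0))

    surface = _peak_surface(params, (cx, cy))
    rib_rows = np.arange(g.n_x) % params.rib_period == params.rib_phase % params.rib_period
    surface[rib_rows, :] *= params.rib_attenuation

    c = np.zeros_like(surface)
    dead = params.dead_zone_columns
    for x in range(g.n_x):
        for y in range(g.n_y):
            if y in dead:
                continue
            cell_true = surface[x, y] + rng.normal() * params.noise_spread
            frames = sample_frames(
                float(np.clip(cell_true, 0.0, 1.0)),
                params.frames_per_cell,
                params.frame_noise_spread,
                rng,
            )
            c[x, y] = aggregate_frames(frames)
    c = np.clip(c, 0.0, 1.0)
    if c.max() <= 0.0:
        raise DegenerateMapError("peak fell entirely inside the dead zone")
    c = _bump_ties(c)
    return ConfidenceMap(subject_id=f"synthetic-{params.seed}", geometry=g, c=c)


def generate_cohort(
    params: MapGenParams, n_subjects: int, seed: int, max_retries: int = 16
) -> list[ConfidenceMap]:
    """Generate ``n_subjects`` maps with independently drawn heart centres.

    Sub-seeds are spawned deterministically from ``seed``; a degenerate draw
    is retried with an advanced sub-seed up to ``max_retries`` times.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    cohort: list[ConfidenceMap] = []
    for i, child in enumerate(children):
        sub_seeds = child.generate_state(max_retries, dtype=np.uint32)
        for attempt in range(max_retries):
            sub = int(sub_seeds[attempt])
            try:
                m = generate_map(dataclasses.replace(params, seed=sub))
            except DegenerateMapError:
                continue
            cohort.append(
                ConfidenceMap(subject_id=f"subject-{i:03d}", geometry=m.geometry, c=m.c)
            )
            break
        else:
            raise DegenerateMapError(
                f"subject {i}: no non-degenerate map within {max_retries} attempts"
            )
    return cohort


# ---------------------------------------------------------------------------
# File dialect: CSV grid (row = X index ascending, column = Y ascending) plus
# a JSON sidecar with subject_id, geometry and provenance.  Confidences are
# written with 17 significant digits, which round-trips float64 exactly.


def write_map(cmap: ConfidenceMap, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, cmap.c, delimiter=",", fmt="%.17g")
    meta = {
        "subject_id": cmap.subject_id,
        "geometry": {"n_x": cmap.geometry.n_x, "n_y": cmap.geometry.n_y},
        "optimal_cell": list(cmap.optimal_cell),
        "c_m": cmap.c_m,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_map(path: str | Path) -> ConfidenceMap:
    path = Path(path)
    c = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    geom = GridGeometry(**meta["geometry"])
    cmap = ConfidenceMap(subject_id=meta["subject_id"], geometry=geom, c=c)
    stored = meta.get("optimal_cell")
    if stored is not None and tuple(stored) != cmap.optimal_cell:
        raise MapValidationError(
            f"stored optimal cell {tuple(stored)} disagrees with recomputed "
            f"argmax {cmap.optimal_cell}"
        )
    return cmap
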