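"""Optimized path generation from a trained search policy, and the
full-coverage baseline.

A greedy rollout of the learned action values alone has three failure modes:
it can oscillate forever between already-visited cells, it can stop on a
zero-confidence cell, and it cannot go back to an optimum it passed through.
The planner fixes these with three rules applied on top of the policy:

* **Revisit masking** — at a cell visited two or more times, take the best
  action among those not already chosen there (masks persist for the whole
  search).
* **Zero-stop recovery** — if the policy stops where the confidence is 0,
  move back (shortest 8-connected path) to the best cell visited so far and
  resume searching from there.
* **Best-visited estimate** — when the search terminates, the estimated
  probe position is the visited cell with the highest confidence, not
  necessarily the stopping cell.

The conventional baseline is the five-way traveling scan: a serpentine sweep
that visits every grid cell once and picks the global argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .confmap import ConfidenceMap, GridGeometry
from .environment import ACTIONS, Action, apply_action

__all__ = [
    "QPolicy",
    "Trajectory",
    "SearchOutcome",
    "VisitLedger",
    "ActionsExhausted",
    "next_action",
    "return_to_best",
    "plan_search",
    "five_way_scan",
    "conventional_estimate",
    "DEFAULT_PLANNER_CAP",
]

DEFAULT_PLANNER_CAP = 500


class QPolicy(Protocol):
    """Anything that scores the nine actions for a probe state."""

    def action_values(self, position: tuple[int, int], c_here: float) -> np.ndarray: ...


class ActionsExhausted(Exception):
    """All nine actions have already been chosen at the current cell."""


@dataclass
class VisitLedger:
    """Per-cell visit counts and the set of actions already chosen there."""

    visits: dict[tuple[int, int], int] = field(default_factory=dict)
    chosen: dict[tuple[int, int], set[Action]] = field(default_factory=dict)

    def record_visit(self, cell: tuple[int, int]) -> None:
        self.visits[cell] = self.visits.get(cell, 0) + 1

    def record_choice(self, cell: tuple[int, int], action: Action) -> None:
        self.chosen.setdefault(cell, set()).add(action)

    def visit_count(self, cell: tuple[int, int]) -> int:
        return self.visits.get(cell, 0)

    def available(self, cell: tuple[int, int]) -> list[Action]:
        used = self.chosen.get(cell, set())
        return [a for a in ACTIONS if a not in used]


@dataclass(frozen=True)
class Trajectory:
    """Ordered visit sequence (including revisits) and the actions taken."""

    visited: tuple[tuple[tuple[int, int], float], ...]
    actions: tuple[Action, ...]
    moves: int


@dataclass(frozen=True)
class SearchOutcome:
    trajectory: Trajectory
    estimated_cell: tuple[int, int]
    c_s: float
    moves: int
    reached_optimal: bool
    termination_reason: str  # stop | cap | exhausted | coverage


def next_action(agent: QPolicy, position: tuple[int, int], c_here: float,
                ledger: VisitLedger) -> Action:
    """Greedy action, masked on revisits.

    At a cell seen two or more times, the argmax runs over the actions not
    yet chosen there; raises :class:`ActionsExhausted` when none remain.
    The chosen action is recorded against the cell.
    """
    q = np.asarray(agent.action_values(position, c_here), dtype=float)
    if ledger.visit_count(position) >= 2:
        candidates = ledger.available(position)
        if not candidates:
            raise ActionsExhausted(position)
    else:
        candidates = list(ACTIONS)
    best = max(candidates, key=lambda a: (q[ACTIONS.index(a)], -ACTIONS.index(a)))
    ledger.record_choice(position, best)
    return best


def _step_toward(current: tuple[int, int], target: tuple[int, int]) -> Action:
    dx = int(np.sign(target[0] - current[0]))
    dy = int(np.sign(target[1] - current[1]))
    for a in ACTIONS:
        if a.displacement == (dx, dy) and a is not Action.STOP:
            return a
    raise ValueError("already at target")


def return_to_best(
    visited: Sequence[tuple[tuple[int, int], float]], geometry: GridGeometry
) -> list[Action]:
    """Moves from the current (last visited) cell back to the best visited
    cell: a Chebyshev-shortest 8-connected path, diagonal-first.  Ties on the
    best confidence go to the earliest-visited cell."""
    if not visited:
        raise ValueError("empty trajectory")
    current = visited[-1][0]
    best_c = max(c for _, c in visited)
    target = next(cell for cell, c in visited if c == best_c)  # earliest among ties
    moves: list[Action] = []
    pos = current
    while pos != target:
        a = _step_toward(pos, target)
        pos, oob = apply_action(pos, a, geometry)
        assert not oob
        moves.append(a)
    return moves


def plan_search(
    agent: QPolicy,
    cmap: ConfidenceMap,
    start: tuple[int, int],
    cap: int = DEFAULT_PLANNER_CAP,
) -> SearchOutcome:
    """Run the full optimized search on one map.

    Iterates the masked greedy policy; applies zero-stop recovery on STOP at
    a zero-confidence cell; terminates on STOP elsewhere, on action
    exhaustion, or at the step cap, and estimates the best visited cell.
    Every executed action — moves, stops, and recovery moves — counts toward
    ``moves``.
    """
    g = cmap.geometry
    if not g.contains(start):
        raise ValueError(f"start {start} outside grid")
    ledger = VisitLedger()
    pos = start
    visited: list[tuple[tuple[int, int], float]] = [(pos, cmap.confidence_at(pos))]
    actions: list[Action] = []
    ledger.record_visit(pos)
    reason = "cap"

    while len(actions) < cap:
        try:
            action = next_action(agent, pos, cmap.confidence_at(pos), ledger)
        except ActionsExhausted:
            reason = "exhausted"
            break
        actions.append(action)
        if action is Action.STOP:
            if cmap.confidence_at(pos) == 0.0:
                # zero-stop recovery: walk back to the best visited cell
                for mv in return_to_best(visited, g):
                    if len(actions) >= cap:
                        break
                    pos, _ = apply_action(pos, mv, g)
                    actions.append(mv)
                    visited.append((pos, cmap.confidence_at(pos)))
                    ledger.record_visit(pos)
                continue
            reason = "stop"
            break
        pos, _ = apply_action(pos, action, g)
        visited.append((pos, cmap.confidence_at(pos)))
        ledger.record_visit(pos)

    best_c = max(c for _, c in visited)
    estimated = next(cell for cell, c in visited if c == best_c)
    traj = Trajectory(visited=tuple(visited), actions=tuple(actions), moves=len(actions))
    return SearchOutcome(
        trajectory=traj,
        estimated_cell=estimated,
        c_s=best_c,
        moves=len(actions),
        reached_optimal=(estimated == cmap.optimal_cell),
        termination_reason=reason,
    )


def five_way_scan(geometry: GridGeometry) -> list[tuple[int, int]]:
    """Serpentine full-coverage path: each lateral column in ascending Y,
    traversing the vertical axis in alternating direction.  Visits every cell
    exactly once in ``n_x * n_y - 1`` moves."""
    cells: list[tuple[int, int]] = []
    for y in range(geometry.n_y):
        xs = range(geometry.n_x) if y % 2 == 0 else range(geometry.n_x - 1, -1, -1)
        cells.extend((x, y) for x in xs)
    return cells


def conventional_estimate(cmap: ConfidenceMap) -> SearchOutcome:
    """The conventional method: full five-way scan, then global argmax.

    Always finds the optimal cell at the cost of ``n_x * n_y - 1`` moves.
    """
    path = five_way_scan(cmap.geometry)
    visited = tuple((cell, cmap.confidence_at(cell)) for cell in path)
    actions = tuple(_step_toward(a, b) for a, b in zip(path[:-1], path[1:]))
    traj = Trajectory(visited=visited, actions=actions, moves=len(actions))
    return SearchOutcome(
        trajectory=traj,
        estimated_cell=cmap.optimal_cell,
        c_s=cmap.c_m,
        moves=len(actions),
        reached_optimal=True,
        termination_reason="coverage",
    )
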