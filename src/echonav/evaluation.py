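"""Evaluation of the search system against the full-coverage baseline.

Accuracy is judged by the confidence at the estimated probe position and the
loss-of-confidence rate ``L_c = 1 - C_s / C_m``; efficiency by the number of
search actions.  Both are compared to the conventional five-way scan through
Cohen's effect size with the pooled standard deviation:
``d = |mean_a - mean_b| / s_pooled``.  Following the effect-size conventions
of the application, accuracy is considered maintained when ``d_C < 0.5`` and
efficiency improved when ``d_A > 0.8``.

Model selection is subject-wise 3-fold cross-validation at a 2:1
train-to-test ratio: the cohort is split into groups A, B, C; model alpha is
trained on A+B and searches C, beta on B+C searches A, gamma on A+C searches
B, so every subject is searched exactly once by a model that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .confmap import ConfidenceMap
from .dqn import DQNAgent, QNetworkConfig, TrainConfig, train
from .environment import RewardParams
from .path_planner import (
    DEFAULT_PLANNER_CAP,
    SearchOutcome,
    conventional_estimate,
    plan_search,
)

__all__ = [
    "GroupStats",
    "OutcomeCategory",
    "TimeParams",
    "CrossValReport",
    "SweepResult",
    "loss_rate",
    "pooled_sd",
    "cohens_d",
    "interpret_effects",
    "categorize_outcome",
    "summarize_outcomes",
    "inspection_time",
    "cross_validate",
    "sweep_parameter",
    "select_best",
]

_EQUALITY_TOL = 1e-12


def loss_rate(c_s: float, c_m: float) -> float:
    """Loss-of-confidence rate ``1 - c_s / c_m`` of an estimated position."""
    if c_m <= 0:
        raise ZeroDivisionError("loss rate undefined for c_m = 0")
    return 1.0 - c_s / c_m


def pooled_sd(a: Sequence[float], b: Sequence[float]) -> float:
    """Pooled sample standard deviation of two groups,
    ``sqrt(((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2))``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size + b.size < 3 or max(a.size, b.size) < 2:
        raise ValueError("need at least three values and one group of >= 2")
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    num = (a.size - 1) * va + (b.size - 1) * vb
    return float(np.sqrt(num / (a.size + b.size - 2)))


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's effect size ``|mean(a) - mean(b)| / pooled_sd(a, b)``."""
    s = pooled_sd(a, b)
    diff = abs(float(np.mean(a)) - float(np.mean(b)))
    if s == 0.0:
        if diff == 0.0:
            return 0.0
        raise ZeroDivisionError("effect size undefined: zero pooled spread")
    return diff / s


def interpret_effects(d_c: float, d_a: float) -> dict[str, bool]:
    """Accuracy maintained iff ``d_C < 0.5``; efficiency improved iff
    ``d_A > 0.8`` (both strict)."""
    return {"accuracy_maintained": d_c < 0.5, "efficiency_improved": d_a > 0.8}


@dataclass(frozen=True)
class GroupStats:
    """Paired proposed/conventional samples with their pooled spread."""

    proposed_values: tuple[float, ...]
    conventional_values: tuple[float, ...]

    @property
    def mean_proposed(self) -> float:
        return float(np.mean(self.proposed_values))

    @property
    def mean_conventional(self) -> float:
        return float(np.mean(self.conventional_values))

    @property
    def pooled(self) -> float:
        return pooled_sd(self.proposed_values, self.conventional_values)

    @property
    def d(self) -> float:
        return cohens_d(self.proposed_values, self.conventional_values)


@dataclass(frozen=True)
class OutcomeCategory:
    confidence_band: str  # "C=C_m" | "0<C<C_m" | "C=0"
    move_band: str  # "<35" | ">=35"


@dataclass(frozen=True)
class TimeParams:
    """Inspection-time model: a constant dwell per visited cell.

    The default 2.45 s/cell scales a 35-cell full scan to the duration of a
    complete conventional inspection; it is a model, not a measurement.
    """

    seconds_per_cell: float = 2.45

    def __post_init__(self) -> None:
        if self.seconds_per_cell <= 0:
            raise ValueError("seconds_per_cell must be > 0")


def inspection_time(outcome: SearchOutcome, time_params: TimeParams = TimeParams()) -> float:
    """Modelled inspection seconds: dwell on every visited cell including the
    start, i.e. ``(moves + 1) * seconds_per_cell``."""
    return (outcome.moves + 1) * time_params.seconds_per_cell


def categorize_outcome(
    outcome: SearchOutcome, c_m: float, threshold: int = 35
) -> OutcomeCategory:
    """Band an outcome by stop confidence (vs ``C_m`` and 0) and move count."""
    if c_m <= 0:
        raise ValueError("c_m must be > 0")
    if abs(outcome.c_s - c_m) <= _EQUALITY_TOL:
        band = "C=C_m"
    elif outcome.c_s <= _EQUALITY_TOL:
        band = "C=0"
    else:
        band = "0<C<C_m"
    return OutcomeCategory(
        confidence_band=band,
        move_band="<35" if outcome.moves < threshold else ">=35",
    )


def summarize_outcomes(
    outcomes: Sequence[SearchOutcome],
    maps: Sequence[ConfidenceMap],
    threshold: int = 35,
) -> pd.DataFrame:
    """3x2 percentage table of outcomes (confidence band x move band) with
    row/column totals; all cells are percentages of all trials."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes to summarize")
    if len(outcomes) != len(maps):
        raise ValueError("outcomes and maps must pair up")
    rows = ["C=C_m", "0<C<C_m", "C=0"]
    cols = ["<35", ">=35"]
    counts = pd.DataFrame(0.0, index=rows, columns=cols)
    for outcome, cmap in zip(outcomes, maps):
        cat = categorize_outcome(outcome, cmap.c_m, threshold)
        counts.loc[cat.confidence_band, cat.move_band] += 1
    pct = counts / len(outcomes) * 100.0
    pct["Total"] = pct.sum(axis=1)
    pct.loc["Total"] = pct.sum(axis=0)
    return pct


@dataclass(frozen=True)
class CrossValReport:
    """Pooled result of subject-wise 3-fold cross-validation."""

    fold_assignments: tuple[int, ...]  # test-fold index per subject
    agents: tuple[DQNAgent, ...]  # (alpha, beta, gamma)
    outcomes: tuple[SearchOutcome, ...]  # one per subject, cohort order
    conventional: tuple[SearchOutcome, ...]
    table: pd.DataFrame = field(repr=False)
    d_c: float
    d_a: float
    mean_loss_rate: float
    mean_loss_rate_nonoptimal: float
    optimal_attainment: float  # fraction of trials reaching the optimum
    mean_moves: float
    mean_time_s: float
    conventional_time_s: float

    @property
    def effects(self) -> dict[str, bool]:
        return interpret_effects(self.d_c, self.d_a)


def _fold_groups(n: int) -> list[list[int]]:
    # contiguous thirds in cohort order (the cohort order is already seeded)
    edges = [round(i * n / 3) for i in range(4)]
    return [list(range(edges[i], edges[i + 1])) for i in range(3)]


def cross_validate(
    cohort: Sequence[ConfidenceMap],
    start: tuple[int, int] = (2, 2),
    reward_params: RewardParams = RewardParams(),
    net_config: QNetworkConfig = QNetworkConfig(),
    train_config: TrainConfig = TrainConfig(),
    planner_cap: int = DEFAULT_PLANNER_CAP,
    time_params: TimeParams = TimeParams(),
) -> CrossValReport:
    """Train alpha/beta/gamma on the 2:1 subject folds and search every
    subject with the model that excluded it; pool outcomes into the
    percentage table, effect sizes and loss-rate summaries."""
    n = len(cohort)
    if n < 3:
        raise ValueError("cross-validation needs at least 3 subjects")
    groups = _fold_groups(n)  # A, B, C
    train_sets = [groups[0] + groups[1], groups[1] + groups[2], groups[0] + groups[2]]
    test_sets = [groups[2], groups[0], groups[1]]  # alpha->C, beta->A, gamma->B

    agents: list[DQNAgent] = []
    outcomes: list[SearchOutcome | None] = [None] * n
    fold_of = [0] * n
    for fold, (tr, te) in enumerate(zip(train_sets, test_sets)):
        cfg = replace(train_config, seed=train_config.seed + fold)
        net_cfg = replace(net_config, init_seed=net_config.init_seed + fold)
        agent, _ = train([cohort[i] for i in tr], start, reward_params, net_cfg, cfg)
        agents.append(agent)
        for i in te:
            outcomes[i] = plan_search(agent, cohort[i], start, cap=planner_cap)
            fold_of[i] = fold

    done: list[SearchOutcome] = [o for o in outcomes if o is not None]
    assert len(done) == n
    conventional = [conventional_estimate(m) for m in cohort]

    prop_c = [o.c_s for o in done]
    conv_c = [o.c_s for o in conventional]
    prop_a = [float(o.moves) for o in done]
    conv_a = [float(o.moves) for o in conventional]
    lrs = [loss_rate(o.c_s, m.c_m) for o, m in zip(done, cohort)]
    lrs_nonopt = [lr for o, lr in zip(done, lrs) if not o.reached_optimal]
    return CrossValReport(
        fold_assignments=tuple(fold_of),
        agents=tuple(agents),
        outcomes=tuple(done),
        conventional=tuple(conventional),
        table=summarize_outcomes(done, cohort),
        d_c=cohens_d(prop_c, conv_c),
        d_a=cohens_d(prop_a, conv_a),
        mean_loss_rate=float(np.mean(lrs)),
        mean_loss_rate_nonoptimal=float(np.mean(lrs_nonopt)) if lrs_nonopt else 0.0,
        optimal_attainment=float(np.mean([o.reached_optimal for o in done])),
        mean_moves=float(np.mean(prop_a)),
        mean_time_s=float(np.mean([inspection_time(o, time_params) for o in done])),
        conventional_time_s=float(
            np.mean([inspection_time(o, time_params) for o in conventional])
        ),
    )


@dataclass(frozen=True)
class SweepResult:
    param: str
    value: object
    d_c: float
    d_a: float
    report: CrossValReport = field(repr=False)


def sweep_parameter(
    cohort: Sequence[ConfidenceMap],
    param: str,
    values: Sequence,
    start: tuple[int, int] = (2, 2),
    reward_params: RewardParams = RewardParams(),
    net_config: QNetworkConfig = QNetworkConfig(),
    train_config: TrainConfig = TrainConfig(),
    **cv_kwargs,
) -> list[SweepResult]:
    """Cross-validate once per value of ``depth_d``, ``m_l`` or ``start`` and
    report the accuracy/efficiency effect sizes for each."""
    if len(values) == 0:
        raise ValueError("empty sweep grid")
    results: list[SweepResult] = []
    for v in values:
        rp, nc, st = reward_params, net_config, start
        if param == "depth_d":
            nc = replace(net_config, depth_d=int(v))
        elif param == "m_l":
            rp = replace(reward_params, m_l=float(v))
        elif param == "start":
            st = tuple(v)
        else:
            raise ValueError(f"unknown sweep parameter {param!r}")
        rep = cross_validate(
            cohort, start=st, reward_params=rp, net_config=nc,
            train_config=train_config, **cv_kwargs,
        )
        results.append(SweepResult(param=param, value=v, d_c=rep.d_c, d_a=rep.d_a,
                                   report=rep))
    return results


def select_best(results: Sequence[SweepResult]) -> SweepResult:
    """Accuracy-first selection: minimal ``d_C``, ties broken by maximal
    ``d_A`` (accuracy outranks efficiency in a clinical system)."""
    return min(results, key=lambda r: (r.d_c, -r.d_a))
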