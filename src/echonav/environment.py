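"""XYC grid-world environment for the probe-search problem.

The agent is the probe tip on the chest grid.  Its state is the probe cell
``(X, Y)`` together with the detection confidence ``C`` observed there; its
nine actions are unit moves in the eight compass directions plus STOP.

The reward shaping has two jobs: make the search fast (small per-move cost,
a large bonus for stopping at the optimal cell within the move budget) and
make it avoid local confidence maxima (a confidence-change term
``delta_gain * (C_after - C_before)`` that pushes the probe uphill, and a
stop penalty ``m_l * (C_m - C_p)`` proportional to how far below the global
optimum the stopping cell's confidence ``C_p`` lies).  All applicable reward
terms sum; each step reports its breakdown so that every contribution can be
audited.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .confmap import ConfidenceMap, GridGeometry

__all__ = [
    "Action",
    "MOVE_ACTIONS",
    "RewardParams",
    "EnvState",
    "StepRecord",
    "RewardContext",
    "apply_action",
    "compute_reward",
    "reset",
    "step",
    "DEFAULT_EPISODE_CAP",
]

DEFAULT_EPISODE_CAP = 100


class Action(Enum):
    """Nine probe actions: eight unit moves and STOP.

    Displacements are (dX, dY): N increases X (toward the head), E increases
    Y (laterally).  The member order is the fixed tie-break order used by
    greedy argmax everywhere in the package.
    """

    N = (1, 0)
    NE = (1, 1)
    E = (0, 1)
    SE = (-1, 1)
    S = (-1, 0)
    SW = (-1, -1)
    W = (0, -1)
    NW = (1, -1)
    STOP = (0, 0)

    @property
    def displacement(self) -> tuple[int, int]:
        return self.value


ACTIONS: tuple[Action, ...] = tuple(Action)
MOVE_ACTIONS: tuple[Action, ...] = tuple(a for a in Action if a is not Action.STOP)


@dataclass(frozen=True)
class RewardParams:
    """The reward terms, with the published defaults.

    The first three make searching costly (per-move, out-of-range and stop
    costs); the last four steer the probe to the optimal solution: the fast
    stop bonus (+20 for stopping at the optimum in under
    ``fast_move_threshold`` moves), the confidence-change gain, the optimal
    stop bonus, and the non-optimal stop penalty slope ``m_l``.
    """

    move_cost: float = -0.1
    out_of_range_cost: float = -0.3
    stop_cost: float = -3.0
    fast_optimal_bonus: float = 20.0
    fast_move_threshold: int = 35
    delta_gain: float = 10.0
    optimal_stop_bonus: float = 5.0
    m_l: float = 40.0

    def __post_init__(self) -> None:
        if self.fast_move_threshold < 1:
            raise ValueError("fast_move_threshold must be >= 1")
        if self.m_l <= 0:
            raise ValueError("m_l must be > 0")


@dataclass(frozen=True)
class EnvState:
    position: tuple[int, int]
    c_here: float
    moves_taken: int
    done: bool = False


@dataclass(frozen=True)
class RewardContext:
    """Everything the reward function looks at for one executed action.

    ``moves_before_stop`` is the number of actions executed before a terminal
    STOP; the fast-stop bonus requires it to be below the threshold (the STOP
    itself does not count against the budget).
    """

    c_before: float
    c_after: float
    action: Action
    out_of_range: bool
    moves_before_stop: int
    stopped_at_optimal: bool
    c_m: float


@dataclass(frozen=True)
class StepRecord:
    state_before: EnvState
    action: Action
    state_after: EnvState
    reward: float
    reward_breakdown: dict[str, float]
    out_of_range: bool


def apply_action(
    position: tuple[int, int], action: Action, geometry: GridGeometry
) -> tuple[tuple[int, int], bool]:
    """Move one cell in the action's direction; clamp at the grid edge.

    STOP and blocked (out-of-range) moves leave the position unchanged; the
    flag is true iff the displaced cell would fall outside the grid.
    """
    if not geometry.contains(position):
        raise ValueError(f"position {position} outside grid")
    if action is Action.STOP:
        return position, False
    dx, dy = action.displacement
    target = (position[0] + dx, position[1] + dy)
    if not geometry.contains(target):
        return position, True
    return target, False


def compute_reward(ctx: RewardContext, params: RewardParams) -> tuple[float, dict[str, float]]:
    """Sum every applicable reward term and report the breakdown.

    Movement actions: move cost, plus the out-of-range cost when the move was
    blocked, plus ``delta_gain * (c_after - c_before)`` (zero for a blocked
    move since the probe did not move).  STOP: stop cost, plus the optimal
    stop bonus — and the fast bonus when under the move budget — when stopped
    at the optimal cell, otherwise minus ``m_l * (c_m - c_p)`` where ``c_p``
    is the confidence at the stopping cell.
    """
    breakdown: dict[str, float] = {}
    if ctx.action is Action.STOP:
        breakdown["stop"] = params.stop_cost
        if ctx.stopped_at_optimal:
            breakdown["optimal_stop_bonus"] = params.optimal_stop_bonus
            if ctx.moves_before_stop < params.fast_move_threshold:
                breakdown["fast_optimal_bonus"] = params.fast_optimal_bonus
        else:
            breakdown["local_stop_penalty"] = -params.m_l * (ctx.c_m - ctx.c_after)
    else:
        breakdown["move"] = params.move_cost
        if ctx.out_of_range:
            breakdown["out_of_range"] = params.out_of_range_cost
        breakdown["delta"] = params.delta_gain * (ctx.c_after - ctx.c_before)
    return sum(breakdown.values()), breakdown


def reset(cmap: ConfidenceMap, start: tuple[int, int]) -> EnvState:
    """Place the probe at the search start cell ``(X_s, Y_s)``."""
    if not cmap.geometry.contains(start):
        raise ValueError(f"start {start} outside grid")
    return EnvState(position=start, c_here=cmap.confidence_at(start), moves_taken=0)


def step(
    state: EnvState,
    action: Action,
    cmap: ConfidenceMap,
    params: RewardParams,
    episode_cap: int = DEFAULT_EPISODE_CAP,
) -> StepRecord:
    """Execute one action: transition, reward, termination.

    The episode ends on STOP or when the executed-action count reaches
    ``episode_cap`` (forced termination carries no stop-condition rewards).
    Blocked moves consume a move and leave the probe in place.
    """
    if state.done:
        raise ValueError("cannot step a terminated episode")
    new_pos, out_of_range = apply_action(state.position, action, cmap.geometry)
    c_after = cmap.confidence_at(new_pos)
    moves_after = state.moves_taken + 1
    stopped_at_optimal = action is Action.STOP and state.position == cmap.optimal_cell
    ctx = RewardContext(
        c_before=state.c_here,
        c_after=c_after,
        action=action,
        out_of_range=out_of_range,
        moves_before_stop=state.moves_taken,
        stopped_at_optimal=stopped_at_optimal,
        c_m=cmap.c_m,
    )
    reward, breakdown = compute_reward(ctx, params)
    done = action is Action.STOP or moves_after >= episode_cap
    after = EnvState(position=new_pos, c_here=c_after, moves_taken=moves_after, done=done)
    return StepRecord(
        state_before=state,
        action=action,
        state_after=after,
        reward=reward,
        reward_breakdown=breakdown,
        out_of_range=out_of_range,
    )
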