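"""Exact tabular action-value oracle for a single confidence map.

On one fixed map the search problem is a tiny deterministic MDP: states are
the grid cells, actions the eight moves plus STOP, transitions are the
clamped unit displacements, and rewards come from the same reward function
the learning environment uses.  Its optimal action-value function can
therefore be computed exactly by synchronous Q-iteration (full Bellman
backups over every state-action pair until the sup-norm change is below
tolerance), with no sampling and no function approximation.  The result
serves as a ground-truth policy to compare the learned network against.

The STOP reward is evaluated with the fast-stop bonus applicable, i.e. the
oracle assumes searches stay within the move budget — which holds on the
small maps this oracle is meant for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .confmap import ConfidenceMap
from .environment import (
    ACTIONS,
    Action,
    RewardContext,
    RewardParams,
    apply_action,
    compute_reward,
)

__all__ = ["TabularQAgent", "solve_tabular_q"]


@dataclass(frozen=True)
class TabularQAgent:
    """Exact per-cell action values; planner-compatible via ``action_values``."""

    cmap: ConfidenceMap
    q: np.ndarray  # shape (n_x, n_y, 9)

    def action_values(self, position: tuple[int, int], c_here: float) -> np.ndarray:
        return self.q[position[0], position[1]]


def solve_tabular_q(
    cmap: ConfidenceMap,
    reward_params: RewardParams,
    gamma: float = 0.95,
    tol: float = 1e-10,
    max_sweeps: int = 10_000,
) -> TabularQAgent:
    """Q-iteration to the exact optimal action values on one map."""
    g = cmap.geometry
    n_actions = len(ACTIONS)
    rewards = np.zeros((g.n_x, g.n_y, n_actions))
    next_x = np.zeros((g.n_x, g.n_y, n_actions), dtype=int)
    next_y = np.zeros((g.n_x, g.n_y, n_actions), dtype=int)
    terminal = np.zeros(n_actions, dtype=bool)

    for x in range(g.n_x):
        for y in range(g.n_y):
            for ai, action in enumerate(ACTIONS):
                pos = (x, y)
                new_pos, oob = apply_action(pos, action, g)
                ctx = RewardContext(
                    c_before=cmap.confidence_at(pos),
                    c_after=cmap.confidence_at(new_pos),
                    action=action,
                    out_of_range=oob,
                    moves_before_stop=0,  # within the fast-stop budget
                    stopped_at_optimal=(
                        action is Action.STOP and pos == cmap.optimal_cell
                    ),
                    c_m=cmap.c_m,
                )
                rewards[x, y, ai], _ = compute_reward(ctx, reward_params)
                next_x[x, y, ai], next_y[x, y, ai] = new_pos
                terminal[ai] = action is Action.STOP

    q = np.zeros((g.n_x, g.n_y, n_actions))
    for _ in range(max_sweeps):
        v_next = q.max(axis=2)[next_x, next_y]
        v_next[:, :, terminal] = 0.0
        q_new = rewards + gamma * v_next
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    return TabularQAgent(cmap=cmap, q=q)
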