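"""Train the Q-network on one small map and compare it with the exact oracle.

On a single 3 x 3 map the search problem is a tiny deterministic MDP, so the
optimal action values can be computed exactly by dynamic programming; a DQN
trained on the same rewards should reproduce the oracle's search outcome.
"""

import numpy as np

from echonav import (
    ConfidenceMap,
    GridGeometry,
    QNetworkConfig,
    RewardParams,
    TrainConfig,
    plan_search,
    solve_tabular_q,
    train,
)

cmap = ConfidenceMap(
    "demo",
    GridGeometry(3, 3),
    np.array([[0.10, 0.20, 0.30],
              [0.15, 0.40, 0.90],
              [0.05, 0.25, 0.60]]),
)
params = RewardParams()

oracle = solve_tabular_q(cmap, params)
oracle_out = plan_search(oracle, cmap, (0, 0))
print(f"oracle: stops via {oracle_out.termination_reason} after "
      f"{oracle_out.moves} actions, estimates {oracle_out.estimated_cell} "
      f"(optimum {cmap.optimal_cell})")

agent, curve = train(
    [cmap], (0, 0), params,
    QNetworkConfig(depth_d=2, init_seed=1),
    TrainConfig(episodes=800, min_replay_before_learning=64, learn_every=2, seed=1),
)
returns = [r["return"] for r in curve]
print(f"DQN: mean return first 80 episodes {np.mean(returns[:80]):+.1f}, "
      f"last 80 episodes {np.mean(returns[-80:]):+.1f}")

dqn_out = plan_search(agent, cmap, (0, 0))
print(f"DQN search: {dqn_out.moves} actions, estimated {dqn_out.estimated_cell}, "
      f"C_s = {dqn_out.c_s:.2f} -> agrees with oracle: "
      f"{dqn_out.estimated_cell == oracle_out.estimated_cell}")
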