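"""Search one synthetic subject with the planner and with the coverage scan.

The conventional method sweeps all 35 cells (34 moves) and picks the argmax;
the optimized planner follows the learned policy with revisit masking,
zero-stop recovery and best-visited estimation, usually needing far fewer
moves.  The loss rate L_c = 1 - C_s / C_m quantifies the confidence given up
when the planner stops short of the optimum.
"""

from echonav import (
    MapGenParams,
    QNetworkConfig,
    RewardParams,
    TrainConfig,
    conventional_estimate,
    generate_cohort,
    inspection_time,
    loss_rate,
    plan_search,
    train,
)

cohort = generate_cohort(MapGenParams(), n_subjects=9, seed=7)
test_map, train_maps = cohort[1], cohort[:1] + cohort[2:]

agent, _ = train(
    train_maps, (2, 2), RewardParams(m_l=40.0),
    QNetworkConfig(depth_d=2, init_seed=0),
    TrainConfig(episodes=3000, seed=0),
)

planned = plan_search(agent, test_map, (2, 2))
scanned = conventional_estimate(test_map)

for name, o in [("planner", planned), ("coverage scan", scanned)]:
    print(f"{name:>14}: {o.moves:>2} moves, estimate {o.estimated_cell}, "
          f"C_s = {o.c_s:.3f}, L_c = {loss_rate(o.c_s, test_map.c_m):.3f}, "
          f"modelled time {inspection_time(o):.1f} s")
print(f"\noptimum is {test_map.optimal_cell} with C_m = {test_map.c_m:.3f}; "
      f"planner reached it: {planned.reached_optimal}")
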