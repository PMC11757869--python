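# echonav

Reinforcement-learning probe navigation for robotic transthoracic
echocardiography, rebuilt as a testable grid-world package.

## The problem

A seated echocardiography robot must place its ultrasound probe on the chest
cell where a heart component — the mitral valve — appears most clearly. The
objective surface is the per-cell object-detection confidence `C ∈ [0, 1]`
(median over the frames acquired at that cell). Ribs cast acoustic shadows at
regular intervals along the body's vertical axis and the sternum/lungs blank
out a central band, so `C` is multimodal: naïve hill climbing stops at a
*local* solution, while the conventional approach — a five-way serpentine
scan of all 35 grid cells followed by the argmax — is accurate but slow.

`echonav` implements the full pipeline around that trade-off:

* **`confmap`** — synthetic per-subject confidence maps with a cardiac peak
  biased to the lower left of the chest, periodic rib-shadow attenuation,
  a zero sternum/lung column, and median-aggregated frame noise; CSV+JSON
  file I/O.
* **`environment`** — the XYC grid world (state = probe cell plus `C`),
  nine actions (8 compass moves + STOP) and the shaped reward: move −0.1,
  out-of-range −0.3, stop −3.0, confidence-change term `10·Δ` with
  `Δ = C_after − C_before`, +5 for stopping at the optimum (+20 more within
  35 moves), and `−m_L·(C_m − C_p)` for stopping anywhere else.
* **`dqn`** — a dense Q-network (D hidden layers × 100 rectifier units over
  the normalized XYC state) trained with epsilon-greedy exploration,
  experience replay and a target network; pure numpy, bit-reproducible from
  its seeds.
* **`path_planner`** — the optimized path generator over the learned policy:
  revisit masking, zero-stop recovery to the best visited cell, and
  best-visited estimation; plus the five-way coverage-scan baseline.
* **`evaluation`** — loss rate `L_c = 1 − C_s/C_m`, Cohen's effect sizes
  `d_C` (accuracy, maintained when < 0.5) and `d_A` (efficiency, improved
  when > 0.8) with pooled SD, the 3×2 outcome table, a dwell-time model,
  subject-wise 3-fold cross-validation (2:1), and parameter sweeps over the
  network depth `D`, the stop-penalty slope `m_L`, and the start cell.
* **`tabular`** — an exact dynamic-programming action-value oracle for small
  maps, used to ground-truth the learned policy.

## Worked example

`examples/04_planner_vs_baseline.py` trains on eight synthetic subjects and
searches a held-out ninth from start cell (2, 2):

```
       planner:  4 moves, estimate (4, 3), C_s = 0.825, L_c = 0.000, modelled time 12.2 s
 coverage scan: 34 moves, estimate (4, 3), C_s = 0.825, L_c = 0.000, modelled time 85.8 s

optimum is (4, 3) with C_m = 0.825; planner reached it: True
```

The planner found the same optimal cell as the exhaustive scan in 4 moves
instead of 34; `L_c = 0` means no detection confidence was given up. The
other examples cover map generation, the reward arithmetic step by step,
oracle-vs-DQN agreement on a tiny map, and cross-validation
(`examples/05_cross_validation.py` prints the pooled outcome table, mean
`L_c`, `d_C`/`d_A` and the modelled inspection times).

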