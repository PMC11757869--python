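# Methods

## The search problem

The probe tip moves on an `n_x × n_y` grid over the chest (default 7 × 5 =
35 cells, origin at the xiphoid process; X caudocranial, Y lateral; 0-based
indices). Each cell carries a detection confidence `C ∈ [0, 1]` for the
mitral valve, defined as the median of the per-frame detector confidences
acquired there. The *optimal solution* is the cell with the global maximum
`C_m`; rib shadows and the sternum/lung band create additional strict local
maxima that a greedy search would mistake for it. The system's goal is to
reach the optimal cell in far fewer probe movements than the 34 moves of the
exhaustive serpentine scan, while giving up as little confidence as possible
when it stops short (`L_c = 1 − C_s/C_m`, with `C_s` the confidence at the
estimated cell).

## Synthetic cohort generator

No public dataset of probe-position confidence grids exists, so the package
generates cohorts whose statistics mimic a chest scan:

| parameter | default | meaning |
|---|---|---|
| `heart_center_mean` | (4.0, 3.0) cells | cardiac peak centre, biased toward the lower-left chest quadrant relative to the probe frame |
| `heart_center_spread` | (0.8, 0.7) cells | per-subject anatomical variation of the peak position |
| `peak_height` | 0.9 | detector confidence over the unobstructed heart |
| `peak_width` | 1.6 cells | squared-exponential decay scale of the peak |
| `rib_period`, `rib_phase` | 2, 1 | every other X row is a rib-shadow row |
| `rib_attenuation` | 0.4 | multiplicative confidence loss on shadow rows |
| `dead_zone_columns` | {0} | sternum/lung band forced to exactly 0 |
| `noise_spread` | 0.02 | per-cell offset (transducer coupling, anatomy) |
| `frames_per_cell`, `frame_noise_spread` | 5, 0.05 | per-frame detector noise, median-aggregated |

The peak is an isotropic squared-exponential; no functional form is implied
by the physics, this one is chosen for a single smooth optimum. With the
default rib model every generated map contains at least one non-global
strict local maximum (verified exhaustively in the tests over 100 seeds), so
the local-solution problem the reward shaping addresses is actually present.
Argmax ties are resolved at generation by bumping the lexicographically
smallest tied cell by the smallest representable increment; maps with a tied
global maximum are rejected at construction, since the search target must be
well defined.

What the generator does **not** emulate: image content (confidences are
sampled, never computed from ultrasound frames), breathing and probe-contact
physics, intra-subject drift between visits to the same cell (a cell's
confidence is fixed within an episode), and non-Gaussian detector failure
modes. Passing tests therefore show that the *algorithms* behave as
specified on landscapes with the stated multimodal structure — not that the
trained policy would transfer to a physical robot.

## Reward design

All applicable reward rows sum. Movement: −0.1 per executed action, −0.3
more when the move would leave the grid (the probe stays in place, the
action still counts — a physical probe cannot leave the chest), plus
`10·(C_after − C_before)`; the confidence-change terms telescope to
`10·(C_end − C_start)` over any trajectory, which the tests assert to
1e-12. STOP: −3.0 always (the stop cost applies even at the optimum; the
rows are treated as independent conditions, and the stacking preserves the
intended ordering of outcomes), +5.0 at the optimal cell, +20.0 more when
the number of actions executed *before* the stop is below 35, and
`−m_L·(C_m − C_p)` at any non-optimal cell, `C_p` being the confidence at
the stopping cell. Stopping at the optimum therefore always strictly
dominates stopping anywhere else, and the non-optimal stop reward rises
monotonically in `C_p` with slope `m_L` (default 40 — the accuracy-first
choice among {10, 20, 40}).

Two deliberate interpretations where the design was open: blocked moves
increment the move counter used by the <35-move bonus (the penalty must not
be escapable), and the terminal STOP itself is excluded from that count.

## Q-network and training

State features are `(X/(n_x−1), Y/(n_y−1), C)`; degenerate single-cell axes
map to 0. The network is `3 → [100]*D → 9` with rectifier hidden units and
a linear output; D defaults to 2 (the depth sweep's accuracy-first choice —
deeper nets overfit the cohort). Training is standard small-scale DQN:
epsilon-greedy (1.0 → 0.05 linearly over the first 60% of episodes),
uniform replay (capacity 10 000, learning starts at 500 transitions, one
Adam minibatch of 32 every 4 environment steps), a target network synced
every 200 learner steps, discount 0.95, and 5000 episodes with maps
scheduled round-robin so a run is bit-reproducible from its seeds. Episodes
are capped at 100 actions; a forced cap termination carries no
stop-condition reward.

The learning rate is 5e-4. With larger steps (1e-3) the policy on some
cohorts converges to Q-values in which STOP is never greedy anywhere, so
planner rollouts only terminate through masking or the step cap and the
move counts balloon; halving the step removed that failure on every cohort
seed tried while slightly improving both effect sizes. The XYC state is
deliberately non-Markov with respect to the fast-stop bonus (the state
excludes the move counter); the bonus acts as return noise that the network
averages over, and the end-to-end evaluation rests on rollout outcomes, not
per-state value accuracy.

## Path planner

The planner wraps the greedy policy with three rules, checked in this
order each iteration: (A) at a cell visited ≥ 2 times, the argmax is taken
over the actions not yet chosen there (masks persist for the whole search;
recovery moves are not charged to the masks since the policy did not choose
them); (B) on STOP at a cell with `C = 0`, the probe walks a
Chebyshev-shortest 8-connected path back to the best visited cell (earliest
among ties) and resumes; (C) on STOP elsewhere — or when a cell's nine
actions are exhausted, or at the global cap of 500 planner steps — the
search ends and the best visited cell is the estimate. Every executed
action, recovery moves included, counts toward the reported move total.
Rule C makes the estimate dominate every visited cell by construction, so
`reached_optimal` is equivalent to having visited the optimum at all.

## Evaluation

Cohen's effect sizes use the standard pooled-SD estimator
`s_p = sqrt(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2))` — the conventional
baseline's confidence values are exactly `C_m` per map and its move count is
the constant 34, so the pooling is dominated by the proposed-side spread.
The outcome table bands `C_s` against `C_m` with tolerance 1e-12 (exact in
practice, because `C_s` is copied from the map) and move counts against the
35-move budget. The inspection-time model is `(moves + 1) × 2.45 s` — a
constant dwell per visited cell calibrated so a full 35-cell scan takes
≈ 86 s; it is a model, never a measurement. Cross-validation splits the
cohort into three contiguous groups A/B/C in (seeded) cohort order, trains
model α on A∪B, β on B∪C, γ on A∪C, and searches C, A and B with α, β and
γ respectively; fold seeds are the run seed plus the fold index, and fold
assignments are returned so every model is reconstructible.

## Problem sizes and determinism

The shipped experiment uses 24 synthetic subjects, 3 folds × 5000 episodes,
and the 7 × 5 grid; a full cross-validation completes in under a minute on
one CPU, and the exact tabular oracle is used on 3 × 3 maps where
Q-iteration converges to machine precision. All randomness flows through
`numpy.random.Generator` objects seeded from explicit integers; generator
sub-seeds are spawned via `SeedSequence`, degenerate maps (peak entirely
inside the dead zone) are resampled from advanced sub-seeds with a bounded
retry budget.

## Known limitations

Grid aspect ratio (7 × 5) and cell pitch are assumptions — only the
35-cell count and example coordinates constrain them; maps are
dimensionless. Probe orientation is fixed (no roll/pitch/yaw actions) and
patient motion is not modelled. Effect sizes on a 24-subject synthetic
cohort are noisy across cohort seeds; the attainment and move-count
properties are stable, the exact `d_A` value is not. The tabular oracle
assumes stops occur within the 35-move budget, which holds on the small
maps it is applied to but would need a move-count state dimension
otherwise.
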