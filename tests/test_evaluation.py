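import statistics

import numpy as np
import pytest

from echonav.confmap import ConfidenceMap, GridGeometry, MapGenParams, generate_cohort
from echonav.dqn import QNetworkConfig, TrainConfig
from echonav.environment import RewardParams
from echonav.evaluation import (
    SweepResult,
    TimeParams,
    categorize_outcome,
    cohens_d,
    cross_validate,
    inspection_time,
    interpret_effects,
    loss_rate,
    pooled_sd,
    select_best,
    summarize_outcomes,
)
from echonav.path_planner import SearchOutcome, Trajectory, conventional_estimate


def _outcome(c_s, moves, cell=(0, 0), reached=False):
    traj = Trajectory(visited=(((0, 0), c_s),), actions=(), moves=moves)
    return SearchOutcome(
        trajectory=traj, estimated_cell=cell, c_s=c_s, moves=moves,
        reached_optimal=reached, termination_reason="stop",
    )


def brute_pooled_sd(a, b):
    va = statistics.variance(a) if len(a) > 1 else 0.0
    vb = statistics.variance(b) if len(b) > 1 else 0.0
    return ((len(a) - 1) * va + (len(b) - 1) * vb) ** 0.5 / (len(a) + len(b) - 2) ** 0.5


class TestLossRate:
    @pytest.mark.parametrize(
        "c_s, c_m, expected", [(0.8, 0.8, 0.0), (0.0, 0.8, 1.0), (0.6, 0.8, 0.25)]
    )
    def test_values(self, c_s, c_m, expected):
        assert loss_rate(c_s, c_m) == pytest.approx(expected)

    def test_undefined_for_zero_optimum(self):
        with pytest.raises(ZeroDivisionError):
            loss_rate(0.5, 0.0)

    def test_unit_interval_whenever_cs_below_cm(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c_m = rng.uniform(0.01, 1.0)
            c_s = rng.uniform(0.0, c_m)
            assert 0.0 <= loss_rate(c_s, c_m) <= 1.0


class TestPooledSd:
    def test_textbook_example(self):
        assert pooled_sd([1, 2, 3], [3, 4, 5]) == pytest.approx(1.0)

    def test_constant_groups(self):
        assert pooled_sd([5, 5, 5], [5, 5, 5]) == 0.0

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.normal(0, 2, rng.integers(2, 12)).tolist()
            b = rng.normal(1, 3, rng.integers(2, 12)).tolist()
            assert pooled_sd(a, b) == pytest.approx(brute_pooled_sd(a, b), rel=1e-12)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            pooled_sd([1.0], [2.0])


class TestCohensD:
    def test_identical_groups_have_zero_effect(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_textbook_example(self):
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(2.0)

    def test_constant_unequal_groups_undefined(self):
        with pytest.raises(ZeroDivisionError):
            cohens_d([1, 1, 1], [2, 2, 2])

    def test_symmetry_shift_and_scale_invariances(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 10)
        b = rng.normal(1, 2, 8)
        d = cohens_d(a, b)
        assert cohens_d(b, a) == pytest.approx(d)
        assert cohens_d(a + 7.0, b + 7.0) == pytest.approx(d)
        assert cohens_d(a * 3.0, b * 3.0) == pytest.approx(d)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.normal(0, 1, int(rng.integers(5, 20)))
            b = rng.normal(0.8, 1.5, int(rng.integers(5, 20)))
            ours = cohens_d(a, b)
            theirs = abs(pingouin.compute_effsize(a, b, eftype="cohen"))
            assert ours == pytest.approx(theirs, rel=1e-9)


class TestInterpretEffects:
    @pytest.mark.parametrize(
        "d_c, d_a, acc, eff",
        [
            (0.19, 1.3, True, True),
            (0.5, 0.8, False, False),
            (0.49, 0.81, True, True),
        ],
    )
    def test_thresholds(self, d_c, d_a, acc, eff):
        assert interpret_effects(d_c, d_a) == {
            "accuracy_maintained": acc,
            "efficiency_improved": eff,
        }


class TestCategorize:
    def test_bands(self):
        assert categorize_outcome(_outcome(0.8, 20), 0.8).confidence_band == "C=C_m"
        assert categorize_outcome(_outcome(0.8, 20), 0.8).move_band == "<35"
        assert categorize_outcome(_outcome(0.0, 10), 0.8).confidence_band == "C=0"
        cat = categorize_outcome(_outcome(0.4, 40), 0.8)
        assert cat.confidence_band == "0<C<C_m" and cat.move_band == ">=35"


class TestSummarize:
    def test_all_optimal_fast(self, map3x3):
        outcomes = [_outcome(map3x3.c_m, 10) for _ in range(4)]
        table = summarize_outcomes(outcomes, [map3x3] * 4)
        assert table.loc["C=C_m", "<35"] == pytest.approx(100.0)
        assert table.loc["Total", "Total"] == pytest.approx(100.0)

    def test_matches_direct_counting(self, map3x3):
        cm = map3x3.c_m
        cases = [(cm, 10), (cm, 40), (0.3, 5), (0.3, 50), (0.0, 3),
                 (cm, 12), (0.2, 36), (cm, 34), (0.0, 40), (0.1, 2)]
        outcomes = [_outcome(c, mv) for c, mv in cases]
        table = summarize_outcomes(outcomes, [map3x3] * 10)
        assert table.loc["C=C_m", "<35"] == pytest.approx(30.0)
        assert table.loc["C=C_m", ">=35"] == pytest.approx(10.0)
        assert table.loc["0<C<C_m", "<35"] == pytest.approx(20.0)
        assert table.loc["0<C<C_m", ">=35"] == pytest.approx(20.0)
        assert table.loc["C=0", "<35"] == pytest.approx(10.0)
        assert table.loc["C=0", ">=35"] == pytest.approx(10.0)
        assert table.loc["Total", "Total"] == pytest.approx(100.0, abs=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_outcomes([], [])


class TestInspectionTime:
    def test_full_scan_duration(self, default_cohort):
        outcome = conventional_estimate(default_cohort[0])
        assert inspection_time(outcome) == pytest.approx(35 * 2.45)

    def test_single_cell(self):
        assert inspection_time(_outcome(0.5, 0)) == pytest.approx(2.45)

    def test_monotone_in_moves(self):
        times = [inspection_time(_outcome(0.5, m)) for m in range(0, 50, 7)]
        assert all(b > a for a, b in zip(times, times[1:]))

    def test_positive_dwell_required(self):
        with pytest.raises(ValueError):
            TimeParams(seconds_per_cell=0.0)


def _fast_cv_kwargs():
    return dict(
        net_config=QNetworkConfig(depth_d=1, init_seed=0),
        train_config=TrainConfig(
            episodes=30, min_replay_before_learning=64, episode_cap=30, seed=0
        ),
        planner_cap=120,
    )


@pytest.fixture(scope="module")
def small_report():
    cohort = generate_cohort(MapGenParams(), 6, seed=11)
    return cohort, cross_validate(cohort, **_fast_cv_kwargs())


class TestCrossValidate:
    def test_every_subject_tested_exactly_once(self, small_report):
        cohort, rep = small_report
        assert len(rep.outcomes) == len(cohort)
        assert sorted(set(rep.fold_assignments)) == [0, 1, 2]
        counts = [rep.fold_assignments.count(f) for f in range(3)]
        assert counts == [2, 2, 2]

    def test_three_models_trained(self, small_report):
        _, rep = small_report
        assert len(rep.agents) == 3

    def test_table_percentages_total_100(self, small_report):
        _, rep = small_report
        assert rep.table.loc["Total", "Total"] == pytest.approx(100.0, abs=0.1)

    def test_conventional_side_is_perfect(self, small_report):
        cohort, rep = small_report
        for outcome, cmap in zip(rep.conventional, cohort):
            assert outcome.c_s == cmap.c_m
            assert outcome.moves == 34

    def test_too_small_cohort_rejected(self, map3x3):
        with pytest.raises(ValueError):
            cross_validate([map3x3, map3x3], **_fast_cv_kwargs())


class TestSweepSelection:
    def test_accuracy_first_rule(self):
        results = [
            SweepResult("m_l", 10, d_c=0.3, d_a=1.0, report=None),
            SweepResult("m_l", 40, d_c=0.2, d_a=0.9, report=None),
        ]
        assert select_best(results).value == 40

    def test_tie_breaks_on_efficiency(self):
        results = [
            SweepResult("depth_d", 2, d_c=0.2, d_a=1.4, report=None),
            SweepResult("depth_d", 4, d_c=0.2, d_a=0.9, report=None),
        ]
        assert select_best(results).value == 2
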