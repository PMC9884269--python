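"""Tests for difficulty estimation, message selection, randomization tests,
position profiles, trend regressions and the bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crowdrate import (
    ExperimentConfig,
    bootstrap_difficulty_uncertainty,
    estimate_difficulty,
    generate_experiment,
    group_fraction_correct,
    moving_average_by_position,
    position_trend,
    randomization_test,
    run_hypothesis_analysis,
    select_messages,
)
from crowdrate.errors import InvalidParameterError, MissingDataError


def _decisions_frame(rows):
    """Minimal hand-built decisions table for arithmetic checks."""
    defaults = {
        "group_id": "g1", "condition": "independent", "subject_position": 1,
        "subject_id": "s1", "ideology": "liberal", "message_id": "m1",
        "veracity": 1, "lean": "liberal", "choice": "rated_true", "correct": 1,
        "displayed_true_count": 0, "displayed_false_count": 0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestEstimateDifficulty:
    def test_complement_arithmetic(self):
        rows = [{"correct": 1}] * 7 + [{"correct": 0}] * 3
        est = estimate_difficulty(_decisions_frame(rows))
        assert est.loc["m1", "d_bar_hat"] == pytest.approx(0.3)

    def test_aligned_subset_fraction(self):
        rows = (
            [{"correct": 1, "ideology": "liberal"}] * 2
            + [{"correct": 0, "ideology": "liberal"}] * 3
            + [{"correct": 1, "ideology": "conservative"}] * 5
        )
        est = estimate_difficulty(_decisions_frame(rows))
        assert est.loc["m1", "d_align_hat"] == pytest.approx(0.6)
        assert est.loc["m1", "n_aligned_decisions"] == 5

    def test_recovers_configured_difficulty_at_scale(self):
        cfg = ExperimentConfig(
            n_segregated_liberal_first=0, n_segregated_conservative_first=0,
            n_integrated=0, n_independent=6, group_size=50, n_per_cell=1,
            d_bar=0.45, bias=0.2, seed=2,
        )
        est = estimate_difficulty(generate_experiment(cfg))
        for _, row in est.iterrows():
            se = np.sqrt(0.45 * 0.55 / row["n_decisions"])
            assert abs(row["d_bar_hat"] - 0.45) <= 3 * se
            d_align = 0.45 - 0.1 * row["veracity"]
            se_a = np.sqrt(d_align * (1 - d_align) / row["n_aligned_decisions"])
            assert abs(row["d_align_hat"] - d_align) <= 3 * se_a

    def test_order_invariance(self, medium_decisions):
        est1 = estimate_difficulty(medium_decisions)
        shuffled = medium_decisions.sample(frac=1, random_state=0)
        est2 = estimate_difficulty(shuffled)
        pd.testing.assert_frame_equal(est1.sort_index(), est2.sort_index())

    def test_missing_independent_decisions_raise(self, medium_decisions):
        no_ind = medium_decisions[medium_decisions["condition"] != "independent"]
        with pytest.raises(MissingDataError):
            estimate_difficulty(no_ind)


class TestSelectMessages:
    @staticmethod
    def _estimates():
        return pd.DataFrame(
            {
                "veracity": [1, 1, -1, -1],
                "lean": ["liberal"] * 4,
                "d_bar_hat": [0.4, 0.6, 0.45, 0.45],
                "d_align_hat": [0.3, 0.4, 0.55, 0.45],
            },
            index=pd.Index(["m1", "m2", "m3", "m4"], name="message_id"),
        )

    def test_h1_thresholds_mean_difficulty(self):
        assert select_messages(self._estimates(), "H1") == ["m1", "m3", "m4"]

    def test_h2_true_messages_easy_for_aligned(self):
        assert select_messages(self._estimates(), "H2") == ["m1"]

    def test_h3_false_messages_hard_for_aligned(self):
        assert select_messages(self._estimates(), "H3") == ["m3"]

    def test_empty_selection_warns(self):
        est = self._estimates().assign(d_bar_hat=0.7)
        with pytest.warns(UserWarning, match="scope"):
            assert select_messages(est, "H1") == []

    def test_boundary_ties_excluded(self):
        est = self._estimates().assign(d_bar_hat=0.5)
        with pytest.warns(UserWarning):
            assert select_messages(est, "H1") == []

    def test_idempotent_and_monotone(self):
        est = self._estimates()
        first = select_messages(est, "H1")
        assert select_messages(est.loc[first], "H1") == first
        stricter = est.assign(d_bar_hat=est["d_bar_hat"] + 0.07)
        assert set(select_messages(stricter, "H1")) <= set(first)

    def test_unknown_hypothesis_rejected(self):
        with pytest.raises(InvalidParameterError):
            select_messages(self._estimates(), "H9")


class TestGroupFraction:
    def test_all_correct_group(self):
        rows = [{"group_id": "g1", "correct": 1}] * 4
        frac = group_fraction_correct(_decisions_frame(rows))
        assert frac.loc["g1"] == 1.0

    def test_simple_ratio(self):
        rows = [{"group_id": "g1", "correct": 1}] * 6 + [
            {"group_id": "g1", "correct": 0}
        ] * 4
        assert group_fraction_correct(_decisions_frame(rows)).loc["g1"] == 0.6

    def test_matches_independent_recount(self, medium_decisions):
        msgs = list(medium_decisions["message_id"].unique()[:3])
        frac = group_fraction_correct(medium_decisions, msgs)
        sub = medium_decisions[medium_decisions["message_id"].isin(msgs)]
        for gid, value in frac.items():
            rows = sub[sub["group_id"] == gid]
            assert value == pytest.approx(rows["correct"].sum() / len(rows))

    def test_empty_subset_errors(self, medium_decisions):
        with pytest.raises(MissingDataError):
            group_fraction_correct(medium_decisions, ["nonexistent"])


class TestRandomizationTest:
    def test_identical_arms_give_p_one(self):
        res = randomization_test([0.5, 0.5], [0.5, 0.5], n_permutations=999, seed=0)
        assert res.ate == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_small_case(self):
        """A = {1,1}, B = {0,0}: 2 of the 6 assignments reach |ATE| = 1."""
        res = randomization_test([1, 1], [0, 0], method="exhaustive")
        assert res.method == "exhaustive"
        assert res.ate == pytest.approx(100.0)
        assert res.p_value == pytest.approx(2 / 6)

    def test_auto_switches_to_exhaustive_for_small_problems(self):
        res = randomization_test([1, 1], [0, 0], n_permutations=1000)
        assert res.method == "exhaustive"

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(8), rng.random(8)
        p1 = randomization_test(a, b, 2000, seed=9, method="monte_carlo").p_value
        p2 = randomization_test(
            5.0 * a - 2.0, 5.0 * b - 2.0, 2000, seed=9, method="monte_carlo"
        ).p_value
        assert p1 == p2

    def test_agrees_with_scipy_permutation_test(self):
        """Independent cross-check against scipy's exact enumeration."""
        a = [0.62, 0.71, 0.55, 0.68]
        b = [0.52, 0.49, 0.58, 0.45]
        ours = randomization_test(a, b, method="exhaustive")
        ref = stats.permutation_test(
            (a, b),
            lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_add_one_convention_keeps_p_positive(self):
        res = randomization_test(
            [1.0] * 6, [0.0] * 6, n_permutations=500, seed=1, method="monte_carlo"
        )
        assert res.p_value == pytest.approx(1 / 501)

    def test_empty_arm_rejected(self):
        with pytest.raises(InvalidParameterError):
            randomization_test([], [0.1], 100)


class TestMovingAverage:
    def test_window_arithmetic(self):
        rows = [
            {"subject_position": p, "correct": c, "group_id": "g1"}
            for p, c in [(1, 1), (2, 0), (3, 1)]
        ]
        prof = moving_average_by_position(_decisions_frame(rows), window=3)
        assert len(prof) == 1
        assert prof.loc[0, "moving_average"] == pytest.approx(2 / 3)

    def test_constant_accuracy_gives_constant_profile(self):
        rows = [
            {"subject_position": p, "correct": 1, "group_id": "g1"}
            for p in range(1, 8)
        ]
        prof = moving_average_by_position(_decisions_frame(rows), window=3)
        assert prof["moving_average"].eq(1.0).all()
        assert prof["position"].min() == 3

    def test_invalid_window_rejected(self, small_decisions):
        with pytest.raises(InvalidParameterError):
            moving_average_by_position(small_decisions, window=0)
        with pytest.raises(InvalidParameterError):
            moving_average_by_position(small_decisions, window=99)

    def test_segregated_false_profile_dips_below_independent(self):
        """Backfiring: early aligned raters of false messages drag the
        segregated profile under the independent one."""
        cfg = ExperimentConfig(
            n_segregated_liberal_first=60,
            n_segregated_conservative_first=0,
            n_integrated=0,
            n_independent=60,
            group_size=50,
            n_per_cell=1,
            seed=13,
        )
        df = generate_experiment(cfg)
        false_lib = df[(df["veracity"] == -1) & (df["lean"] == "liberal")]
        prof = moving_average_by_position(false_lib, window=3)
        seg = prof[prof["condition"] == "segregated_liberal_first"]
        ind = prof[prof["condition"] == "independent"]
        merged = seg.merge(ind, on="position", suffixes=("_seg", "_ind"))
        early = merged[merged["position"] <= 25]
        assert (
            early["moving_average_seg"].mean()
            < early["moving_average_ind"].mean() - 0.02
        )


class TestPositionTrend:
    @staticmethod
    def _simulate_trend(beta, n_groups=40, n_pos=30, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_groups):
            pos = np.arange(1, n_pos + 1)
            p = 1 / (1 + np.exp(-(0.1 + beta * pos)))
            correct = rng.random(n_pos) < p
            for i, c in zip(pos, correct):
                rows.append(
                    {
                        "group_id": f"g{g}", "subject_position": int(i),
                        "correct": int(c),
                    }
                )
        return _decisions_frame(rows)

    def test_recovers_positive_slope(self):
        """Known log-odds slope falls inside the 95% CI in most replicates."""
        hits, positive = 0, 0
        for rep in range(30):
            df = self._simulate_trend(0.05, seed=rep)
            res = position_trend(df)
            assert res.flag is None
            positive += res.beta > 0
            if abs(res.beta - 0.05) <= 1.96 * res.se:
                hits += 1
        assert positive >= 27
        assert hits >= 24

    def test_null_slope_rarely_significant(self):
        sig = 0
        for rep in range(30):
            df = self._simulate_trend(0.0, seed=100 + rep)
            res = position_trend(df)
            sig += res.p_value < 0.05
        assert sig <= 5

    def test_degenerate_outcome_flagged(self):
        rows = [
            {"subject_position": p, "correct": 1, "group_id": "g1"}
            for p in range(1, 10)
        ]
        res = position_trend(_decisions_frame(rows))
        assert res.flag == "degenerate"
        assert res.beta is None

    def test_empty_stratum_errors(self, small_decisions):
        with pytest.raises(MissingDataError):
            position_trend(small_decisions, ideology="liberal", veracity=7)


class TestBootstrap:
    def test_degenerate_input_zero_width(self):
        rows = [{"correct": 1}] * 12
        boot = bootstrap_difficulty_uncertainty(
            _decisions_frame(rows), n_boot=100, seed=0
        )
        assert boot.loc["m1", "d_bar_lo"] == boot.loc["m1", "d_bar_hi"] == 0.0
        assert boot.loc["m1", "flip_rate_d_bar"] == 0.0

    def test_boundary_estimate_flips_half_the_time(self):
        rows = [{"correct": 1}] * 100 + [{"correct": 0}] * 100
        boot = bootstrap_difficulty_uncertainty(
            _decisions_frame(rows), n_boot=400, seed=1
        )
        assert boot.loc["m1", "flip_rate_d_bar"] == pytest.approx(0.5, abs=0.1)

    def test_intervals_bracket_configured_difficulty(self):
        cfg = ExperimentConfig(
            n_segregated_liberal_first=0, n_segregated_conservative_first=0,
            n_integrated=0, n_independent=6, group_size=50, n_per_cell=1,
            seed=3,
        )
        df = generate_experiment(cfg)
        boot = bootstrap_difficulty_uncertainty(df, n_boot=300, seed=4)
        covered = (
            (boot["d_bar_lo"] <= 0.45) & (0.45 <= boot["d_bar_hi"])
        ).sum()
        assert covered >= 3  # 4 messages, nominal 95% intervals


class TestHypothesisPipeline:
    def test_h1_to_h3_labels_and_directions(self, rng):
        df = generate_experiment(ExperimentConfig(seed=123))
        est = estimate_difficulty(df)
        res1 = run_hypothesis_analysis(df, "H1", 500, seed=0, estimates=est)
        labels = {t.label for t in res1["tests"]}
        assert {"H1_liberal", "H1_conservative", "H1_all"} == labels
        res2 = run_hypothesis_analysis(df, "H2", 500, seed=0, estimates=est)
        assert all(t.ate > 0 for t in res2["tests"])
        res3 = run_hypothesis_analysis(df, "H3", 500, seed=0, estimates=est)
        t3 = [t for t in res3["tests"] if t.label == "H3_all"][0]
        assert t3.ate < 0
        assert t3.n_groups == 60

    def test_h4_h5_strata(self, rng):
        df = generate_experiment(ExperimentConfig(seed=123))
        res = run_hypothesis_analysis(df, "H4", 100, seed=0)
        strata = {t.stratum for t in res["trends"]}
        assert strata == {
            "H4a_liberal", "H4b_conservative", "H4a_conservative", "H4b_liberal"
        }
        for t in res["trends"]:
            assert t.n_decisions == 2500
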