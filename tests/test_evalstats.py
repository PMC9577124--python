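"""Evaluation suite: published worked examples and independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from pcai import synthio
from pcai.cohort import derive_bad_outcome
from pcai.evalstats import (
    ConfusionMatrix2,
    SurvivalInput,
    auc,
    auc_bootstrap_ci,
    auc_permutation_test,
    balanced_accuracy,
    bin_pcai,
    case_score,
    cox_hr,
    km_curve,
    weighted_kappa,
)

# confusion matrices [tn, fp, fn, tp] with their published balanced accuracies
PUBLISHED_MATRICES = [
    ((514, 197, 109, 288), 0.724),
    ((659, 52, 167, 230), 0.753),
    ((513, 121, 56, 288), 0.823),
    ((595, 39, 129, 215), 0.782),
    ((76, 36, 22, 67), 0.716),
    ((79, 33, 28, 61), 0.695),
    ((106, 6, 32, 57), 0.793),
    ((76, 21, 9, 67), 0.833),
    ((76, 21, 15, 61), 0.793),
    ((94, 3, 23, 53), 0.833),
]

# 7x7 agreement counts between the two graders (rows: grader 2, cols: grader 1)
PATHOLOGIST_AGREEMENT = np.array(
    [
        [52, 77, 23, 37, 9, 4, 2],
        [18, 65, 67, 118, 51, 18, 14],
        [1, 2, 10, 34, 17, 17, 18],
        [0, 1, 0, 18, 9, 11, 16],
        [1, 1, 0, 2, 4, 18, 22],
        [0, 0, 0, 1, 1, 5, 18],
        [0, 0, 0, 0, 1, 4, 21],
    ]
)


def pair_counting_auc(scores, labels) -> float:
    """Brute-force AUC: concordant (pos, neg) pair fraction, half for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBalancedAccuracy:
    @pytest.mark.parametrize("counts,expected", PUBLISHED_MATRICES)
    def test_matches_published_tables(self, counts, expected):
        tn, fp, fn, tp = counts
        value = balanced_accuracy(ConfusionMatrix2(tn=tn, fp=fp, fn=fn, tp=tp))
        assert round(value, 3) == expected

    def test_perfect_classifier(self):
        assert balanced_accuracy(ConfusionMatrix2(tn=10, fp=0, fn=0, tp=7)) == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(ConfusionMatrix2(tn=5, fp=5, fn=0, tp=0))

    def test_polarity_swap_invariance(self, rng):
        tn, fp, fn, tp = rng.integers(1, 100, size=4)
        a = balanced_accuracy(ConfusionMatrix2(tn=tn, fp=fp, fn=fn, tp=tp))
        b = balanced_accuracy(ConfusionMatrix2(tn=tp, fp=fn, fn=fp, tp=tn))
        assert a == pytest.approx(b)


class TestAUC:
    def test_equals_pair_counting_oracle_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 6, size=n) / 5.0  # quantised -> ties
            assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))

    def test_six_point_toy_set(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.9]
        labels = [0, 0, 1, 1, 0, 1]
        assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])

    def test_bootstrap_ci_degenerates_for_perfect_separation(self, rng):
        scores = [0.1, 0.2, 0.3, 0.8, 0.9, 0.95]
        labels = [0, 0, 0, 1, 1, 1]
        point, lo, hi = auc_bootstrap_ci(scores, labels, n_boot=200, rng=rng)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        scores = rng.normal(size=200) + np.repeat([0, 1], 100)
        labels = np.repeat([0, 1], 100)
        point, lo, hi = auc_bootstrap_ci(scores, labels, n_boot=300, rng=rng)
        assert lo <= point <= hi and hi - lo < 0.25

    def test_case_level_resampling_keeps_cases_together(self, rng):
        scores = np.linspace(0, 1, 40)
        labels = (scores > 0.5).astype(int)
        case_ids = np.repeat(np.arange(20), 2)
        point, lo, hi = auc_bootstrap_ci(scores, labels, n_boot=100, rng=rng, case_ids=case_ids)
        assert point == 1.0 and lo <= hi


class TestPermutationTest:
    def test_identical_predictors_give_p_one(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        assert auc_permutation_test(scores, scores, labels, n_perm=50, rng=rng) == 1.0

    def test_symmetric_in_predictor_order(self, rng):
        a, b = rng.random(40), rng.random(40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        p1 = auc_permutation_test(a, b, labels, n_perm=200, rng=np.random.default_rng(4))
        p2 = auc_permutation_test(b, a, labels, n_perm=200, rng=np.random.default_rng(4))
        assert p1 == p2

    def test_add_one_smoothing_bounds_p_away_from_zero(self, rng):
        labels = np.repeat([0, 1], 15)
        strong = labels + rng.normal(0, 0.01, 30)
        noise = rng.random(30)
        p = auc_permutation_test(strong, noise, labels, n_perm=99, rng=rng)
        assert p >= 1 / 100

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            auc_permutation_test([0.1, 0.2], [0.3], [0, 1])


class TestWeightedKappa:
    def test_published_seven_by_seven_agreement(self):
        assert weighted_kappa(PATHOLOGIST_AGREEMENT) == pytest.approx(0.29, abs=0.005)

    def test_diagonal_matrix_is_perfect_agreement(self):
        assert weighted_kappa(np.diag([5, 3, 9])) == 1.0

    def test_independent_raters_score_zero(self):
        rows, cols = np.array([10, 20, 5.0]), np.array([8, 4, 23.0])
        m = np.outer(rows, cols) / (rows.sum())
        assert weighted_kappa(m) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        m = PATHOLOGIST_AGREEMENT
        assert weighted_kappa(m) == pytest.approx(weighted_kappa(m * 3.7))

    def test_binary_case_equals_unweighted_cohen_kappa(self, rng):
        m = rng.integers(1, 30, size=(2, 2))
        a = np.repeat([0, 0, 1, 1], m.ravel())
        b = np.repeat([0, 1, 0, 1], m.ravel())
        assert weighted_kappa(m) == pytest.approx(cohen_kappa_score(a, b))

    def test_linear_weights_match_sklearn_on_larger_matrix(self):
        m = PATHOLOGIST_AGREEMENT
        a = np.repeat(np.repeat(np.arange(7), 7), m.ravel())
        b = np.repeat(np.tile(np.arange(7), 7), m.ravel())
        assert weighted_kappa(m) == pytest.approx(
            cohen_kappa_score(a, b, weights="linear")
        )

    def test_rectangular_matrix_rejected(self):
        with pytest.raises(ValueError, match="square"):
            weighted_kappa(np.ones((5, 7)))

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa(np.array([[7, 0], [0, 0]]))


class TestBinning:
    def test_published_row_label_for_low_score(self):
        idx, labels = bin_pcai([0.15], n_bins=5)
        assert labels[idx[0]] == "0.0-0.2"

    def test_top_boundary_right_closed(self):
        idx, labels = bin_pcai([1.0, 0.999], n_bins=5)
        assert idx[0] == idx[1] == 4

    def test_seven_bin_edges(self):
        idx, labels = bin_pcai(np.linspace(0, 1, 50), n_bins=7)
        assert len(labels) == 7
        # a score just below k/7 lands in bin k-1
        for k in range(1, 7):
            i, _ = bin_pcai([k / 7 - 1e-9], n_bins=7)
            assert i[0] == k - 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_pcai([1.2])


class TestCaseScore:
    def test_maximum_rule(self):
        assert case_score([0.2, 0.9, 0.5]) == 0.9
        assert case_score([0.42]) == 0.42
        assert case_score([0.5, 0.9, 0.2]) == case_score([0.9, 0.2, 0.5])

    def test_no_assessable_spots_rejected(self):
        with pytest.raises(ValueError):
            case_score([])


class TestKaplanMeier:
    def test_no_events_stays_at_one(self):
        surv = SurvivalInput(
            time_years=np.array([1.0, 2, 3]), event=np.zeros(3, dtype=bool),
            score=np.zeros(3),
        )
        curves = km_curve(surv, groups=np.zeros(3))
        assert (curves["0.0"]["survival"] == 1.0).all()

    def test_five_case_hand_computed_product_limit(self):
        # times 1,2,3,4,5; events 1,1,0,1,0:
        # S(1) = 4/5 = 0.8; S(2) = 0.8 * 3/4 = 0.6; censor at 3;
        # S(4) = 0.6 * 1/2 = 0.3; censored at 5 leaves 0.3
        surv = SurvivalInput(
            time_years=np.array([1.0, 2, 3, 4, 5]),
            event=np.array([1, 1, 0, 1, 0], dtype=bool),
            score=np.zeros(5),
        )
        df = km_curve(surv, groups=np.zeros(5))["0.0"].set_index("time")
        assert df.loc[1.0, "survival"] == pytest.approx(0.8)
        assert df.loc[2.0, "survival"] == pytest.approx(0.6)
        assert df.loc[4.0, "survival"] == pytest.approx(0.3)
        assert df.loc[5.0, "survival"] == pytest.approx(0.3)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(2.0, size=60)
        surv = SurvivalInput(
            time_years=times, event=np.ones(60, dtype=bool), score=np.zeros(60)
        )
        df = km_curve(surv, groups=np.zeros(60))["0.0"]
        for t, s in zip(df["time"], df["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)


class TestCox:
    def test_null_score_gives_unit_hazard_and_half_concordance(self, rng):
        n = 500
        times = rng.exponential(3.0, size=n)
        result = cox_hr(
            SurvivalInput(
                time_years=times, event=np.ones(n, dtype=bool), score=rng.random(n)
            ),
            unit=1.0,
        )
        assert result.ci_low <= 1.0 <= result.ci_high
        assert abs(result.concordance - 0.5) < 0.05

    def test_unit_scaling_relation(self, rng):
        n = 300
        score = rng.random(n)
        times = rng.exponential(1.0 / np.exp(1.5 * score))
        surv = SurvivalInput(time_years=times, event=np.ones(n, dtype=bool), score=score)
        per_unit = cox_hr(surv, unit=1.0).hazard_ratio
        per_tenth = cox_hr(surv, unit=0.1).hazard_ratio
        assert per_tenth == pytest.approx(per_unit ** 0.1, rel=1e-6)

    def test_recovers_planted_log_hazard_within_two_se(self):
        """The generator's log-hazard effect is recovered from 1000 cases."""
        config = synthio.WorldConfig(n_tmas=20, cases_per_tma=50, seed=21)
        world = synthio.generate_cohort(config)
        outcomes = [derive_bad_outcome(c) for c in world.cases]
        surv = SurvivalInput(
            time_years=np.array([o.time_years for o in outcomes]),
            event=np.array([o.occurred for o in outcomes]),
            score=np.array([world.latents[c.case_id] for c in world.cases]),
        )
        result = cox_hr(surv, unit=1.0)
        log_hr = np.log(result.hazard_ratio)
        se = (np.log(result.ci_high) - np.log(result.ci_low)) / (2 * 1.96)
        assert abs(log_hr - config.log_hazard_beta) < 2 * se

    def test_no_events_rejected(self):
        surv = SurvivalInput(
            time_years=np.ones(5), event=np.zeros(5, dtype=bool), score=np.ones(5)
        )
        with pytest.raises(ValueError):
            cox_hr(surv)

    def test_missing_adjustment_covariate_rejected(self, rng):
        surv = SurvivalInput(
            time_years=rng.exponential(size=20), event=np.ones(20, dtype=bool),
            score=rng.random(20),
        )
        with pytest.raises(ValueError, match="age"):
            cox_hr(surv, adjust=["age"])

    def test_age_psa_adjustment_runs(self, rng):
        n = 200
        surv = SurvivalInput(
            time_years=rng.exponential(2, size=n), event=np.ones(n, dtype=bool),
            score=rng.random(n), age=rng.normal(64, 6, n), psa=rng.lognormal(2, 0.5, n),
        )
        result = cox_hr(surv, unit=0.1, adjust=["age", "psa"])
        assert result.hazard_ratio > 0
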