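import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gosepred.metrics import (
    accuracy_within,
    calibration_curve,
    category_proportion_discrepancy,
    confusion_matrix,
    dichotomized_auroc,
    discrepancy_stats,
    error_distribution,
    full_report,
    one_vs_rest_stats,
)
from gosepred.predictors import PredictionSet

labels_strategy = st.lists(st.integers(1, 8), min_size=1, max_size=60)
paired_labels = st.integers(1, 60).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(1, 8), min_size=n, max_size=n),
        st.lists(st.integers(1, 8), min_size=n, max_size=n),
    )
)


def make_pset(pred, obs):
    pred = np.asarray(pred, dtype=int)
    probs = np.zeros((pred.size, 8))
    probs[np.arange(pred.size), pred - 1] = 1.0
    return PredictionSet(observed=np.asarray(obs), predicted=pred, probabilities=probs)


class TestAccuracyWithin:
    def test_k0(self):
        assert accuracy_within([1, 3, 8, 5], [2, 3, 6, 5], 0) == 0.5

    def test_k1(self):
        assert accuracy_within([1, 3, 8, 5], [2, 3, 6, 5], 1) == 0.75

    def test_k7_always_one(self):
        assert accuracy_within([1, 1, 1], [8, 8, 8], 7) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy_within([], [], 0)

    @given(paired_labels, st.integers(0, 6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_k(self, pair, k):
        pred, obs = pair
        assert accuracy_within(pred, obs, k) <= accuracy_within(pred, obs, k + 1)


class TestDiscrepancy:
    def test_maximal_optimism(self):
        md, sdd = discrepancy_stats([8, 8], [1, 1])
        assert md == 7.0

    def test_identity(self):
        md, sdd = discrepancy_stats([3, 5, 7], [3, 5, 7])
        assert md == 0.0 and sdd == 0.0

    def test_hand_computed_sdd(self):
        # sd(pred)=0; sample sd of (1,3,5,7) = sqrt(20/3)
        md, sdd = discrepancy_stats([4, 4, 4, 4], [1, 3, 5, 7])
        assert md == 0.0
        assert sdd == pytest.approx(-np.sqrt(20 / 3), abs=1e-12)

    def test_sdd_nan_for_single(self):
        md, sdd = discrepancy_stats([4], [2])
        assert md == 2.0 and np.isnan(sdd)

    @given(paired_labels)
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, pair):
        pred, obs = pair
        pred, obs = np.array(pred), np.array(obs)
        perm = np.random.default_rng(0).permutation(pred.size)
        a = discrepancy_stats(pred, obs)
        b = discrepancy_stats(pred[perm], obs[perm])
        assert a[0] == pytest.approx(b[0])
        if pred.size > 1:
            assert a[1] == pytest.approx(b[1])


class TestCategoryProportions:
    def test_disjoint_support_extremes(self):
        pcp, ocp, tcpd, mcpd = category_proportion_discrepancy([8] * 10, [1] * 10)
        assert tcpd == 2.0 and mcpd == 1.0

    def test_permutation_gives_zero(self):
        obs = [1, 3, 3, 5, 8, 8, 8]
        pred = [8, 8, 8, 5, 3, 3, 1]
        _, _, tcpd, mcpd = category_proportion_discrepancy(pred, obs)
        assert tcpd == 0.0 and mcpd == 0.0

    def test_four_patient_enumeration(self):
        pcp, ocp, tcpd, mcpd = category_proportion_discrepancy(
            [1, 1, 2, 2], [1, 1, 1, 2]
        )
        np.testing.assert_allclose(pcp[:2], [0.5, 0.5])
        np.testing.assert_allclose(ocp[:2], [0.75, 0.25])
        assert tcpd == pytest.approx(0.5)
        assert mcpd == pytest.approx(0.25)

    @given(paired_labels)
    @settings(max_examples=100, deadline=None)
    def test_invariants(self, pair):
        pred, obs = pair
        pcp, ocp, tcpd, mcpd = category_proportion_discrepancy(pred, obs)
        assert pcp.sum() == pytest.approx(1.0)
        assert ocp.sum() == pytest.approx(1.0)
        assert 0.0 <= tcpd <= 2.0
        assert 0.0 <= mcpd <= 1.0
        assert mcpd <= tcpd <= 8 * mcpd + 1e-12


class TestOneVsRest:
    def test_perfect_predictions(self):
        labels = list(range(1, 9))
        aba, prec, rec, spec = one_vs_rest_stats(labels, labels)
        assert aba == prec == rec == spec == 1.0

    def test_hand_confusion(self):
        # class 1: sens .5 spec 1; class 2: sens 1 spec .5 -> ABA .75
        aba, prec, rec, spec = one_vs_rest_stats([1, 2, 2], [1, 1, 2])
        assert aba == pytest.approx(0.75)

    def test_never_predicted_category(self):
        # category 2 in obs never predicted: recall_2 = 0, precision_2 excluded
        aba, prec, rec, spec = one_vs_rest_stats([1, 1, 1, 1], [1, 1, 2, 2])
        assert rec == pytest.approx(np.mean([1.0, 0.0]))
        assert prec == pytest.approx(0.5)  # only category 1 has predictions


class TestAuroc:
    def brute_force(self, scores, positives):
        pos = scores[positives]
        neg = scores[~positives]
        total = 0.0
        for a in pos:
            for b in neg:
                total += 1.0 if a > b else (0.5 if a == b else 0.0)
        return total / (len(pos) * len(neg))

    def test_perfect_separation(self):
        probs = np.zeros((4, 8))
        probs[:, 0] = [0.9, 0.8, 0.1, 0.2]
        probs[:, 7] = 1 - probs[:, 0]
        assert dichotomized_auroc(probs, [1, 1, 5, 6], "mortality") == 1.0

    def test_all_ties_half(self):
        probs = np.full((6, 8), 0.125)
        assert dichotomized_auroc(probs, [1, 1, 2, 5, 6, 8], "mortality") == 0.5

    def test_hand_pair_counting(self):
        probs = np.zeros((4, 8))
        probs[:, 0] = [0.8, 0.6, 0.4, 0.2]
        probs[:, 7] = 1 - probs[:, 0]
        assert dichotomized_auroc(probs, [1, 5, 1, 5], "mortality") == 0.75

    def test_unfavorable_uses_p1_to_p4(self):
        probs = np.zeros((2, 8))
        probs[0, :4] = 0.25  # sum 1 -> score 1.0
        probs[1, 4:] = 0.25  # score 0.0
        assert dichotomized_auroc(probs, [2, 7], "unfavorable") == 1.0

    def test_one_class_returns_nan_with_warning(self):
        probs = np.full((3, 8), 0.125)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(dichotomized_auroc(probs, [5, 6, 7], "mortality"))

    @given(
        st.integers(2, 12).flatmap(
            lambda n: st.tuples(
                st.lists(
                    st.floats(0, 1, allow_nan=False, width=16), min_size=n, max_size=n
                ),
                st.lists(st.booleans(), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_rank_equals_pair_counting(self, data):
        scores, flags = data
        scores = np.asarray(scores)
        positives = np.asarray(flags)
        if positives.all() or not positives.any():
            return
        from gosepred.metrics import _rank_auroc

        assert _rank_auroc(scores, positives) == pytest.approx(
            self.brute_force(scores, positives), abs=1e-12
        )


class TestConfusionAndErrors:
    def test_identity_diagonal(self):
        labels = list(range(1, 9))
        mat = confusion_matrix(labels, labels)
        assert np.array_equal(mat, np.eye(8, dtype=int))

    def test_orientation_rows_observed(self):
        mat = confusion_matrix(pred=[8], obs=[1])
        assert mat[0, 7] == 1 and mat[7, 0] == 0

    @given(paired_labels)
    @settings(max_examples=50, deadline=None)
    def test_trace_over_n_is_accuracy(self, pair):
        pred, obs = pair
        mat = confusion_matrix(pred, obs)
        assert mat.trace() / len(pred) == pytest.approx(accuracy_within(pred, obs, 0))
        assert mat.sum() == len(pred)

    def test_empty_confusion_is_zero(self):
        assert confusion_matrix([], []).sum() == 0

    def test_error_distribution_identity(self):
        hist = error_distribution([3, 4], [3, 4])
        assert hist[0] == 2 and sum(hist.values()) == 2

    def test_error_distribution_sign(self):
        # prediction above observation -> negative (overestimated prognosis)
        hist = error_distribution(pred=[8], obs=[1])
        assert hist[-7] == 1

    @given(paired_labels)
    @settings(max_examples=50, deadline=None)
    def test_error_histogram_total(self, pair):
        pred, obs = pair
        assert sum(error_distribution(pred, obs).values()) == len(pred)


class TestCalibration:
    def test_constant_probability_single_bin(self):
        rng = np.random.default_rng(0)
        n = 1000
        probs = np.full((n, 8), 0.125)
        obs = rng.integers(1, 9, size=n)
        with pytest.warns(RuntimeWarning, match="merged"):
            curve = calibration_curve(probs, obs, category=1, n_bins=10)
        assert len(curve.bins) == 1
        mean_pred, freq, se, count = curve.bins[0]
        assert mean_pred == pytest.approx(0.125)
        assert abs(freq - 0.125) < 3 * se + 1e-9
        assert count == n

    def test_bin_counts_sum_to_n(self, rng):
        n = 500
        raw = rng.uniform(size=(n, 8))
        probs = raw / raw.sum(1, keepdims=True)
        obs = rng.integers(1, 9, size=n)
        curve = calibration_curve(probs, obs, category=3, n_bins=10)
        assert curve.total == n

    def test_true_model_is_calibrated(self):
        # oracle: feeding generative probabilities must calibrate within
        # binomial error at n=50,000
        from gosepred.synthetic import profile_config, simulate_cohort, true_probabilities

        config = profile_config("uppsala", n=50_000, seed=31)
        cohort = simulate_cohort(config)
        probs = true_probabilities(config, cohort)
        obs = cohort.data["gose"].to_numpy(int)
        for category in (1, 3, 8):
            curve = calibration_curve(probs, obs, category=category, n_bins=10)
            worst = max(abs(m - f) for m, f, _, _ in curve.bins)
            assert worst < 0.02


class TestFullReport:
    def test_perfect_predictions(self):
        labels = np.array(list(range(1, 9)) * 3)
        report = full_report(make_pset(labels, labels))
        assert report.accuracy == report.aw1 == report.aw2 == 1.0
        assert report.md == report.sdd == 0.0
        assert report.tcpd == report.mcpd == 0.0
        assert report.aba == 1.0

    def test_report_invariants_fuzzed(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 80))
            pred = rng.integers(1, 9, size=n)
            obs = rng.integers(1, 9, size=n)
            report = full_report(make_pset(pred, obs))
            assert report.accuracy <= report.aw1 <= report.aw2 <= 1.0
            assert 0 <= report.tcpd <= 2 and 0 <= report.mcpd <= 1
            assert report.mcpd <= report.tcpd <= 8 * report.mcpd + 1e-12
            assert report.confusion.sum() == n
            assert report.confusion.trace() / n == pytest.approx(report.accuracy)
            assert report.pcp.sum() == pytest.approx(1.0)
            assert report.ocp.sum() == pytest.approx(1.0)

    def test_table_row_shape(self):
        labels = np.array([1, 2, 3, 4, 5, 6, 7, 8])
        report = full_report(make_pset(labels, labels))
        from gosepred.metrics import MetricReport

        assert len(report.table_row().split("\t")) == len(
            MetricReport.table_header().split("\t")
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            full_report(
                PredictionSet(
                    observed=np.empty(0, dtype=int),
                    predicted=np.empty(0, dtype=int),
                    probabilities=np.empty((0, 8)),
                )
            )
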