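"""Evaluation machinery: hand oracles, brute-force AUC, Monte-Carlo checks."""

import numpy as np
import pandas as pd
import pytest

from dpetfusion.metrics import (
    auc,
    baseline_clinical_model,
    bootstrap_ci,
    decision_curve,
    hanley_mcneil,
    hanley_mcneil_variance,
    pr_curve,
    probability_density,
    reconstruct_confusion,
    roc_points,
    threshold_metrics,
    threshold_response,
)


class TestAuc:
    def test_matches_brute_force_pair_counting(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 50))
            probs = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            pos = probs[labels == 1]
            neg = probs[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(probs, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_equals_trapezoidal_roc_area(self, rng):
        probs = rng.random(80)
        labels = rng.integers(0, 2, 80)
        pts = roc_points(probs, labels)
        trapz = float(np.trapezoid(pts["tpr"], pts["fpr"]))
        assert auc(probs, labels) == pytest.approx(trapz, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestThresholdMetrics:
    def test_hand_confusion_matrix(self):
        # TP=20, FN=2, TN=11, FP=6
        probs = np.array([0.9] * 20 + [0.1] * 2 + [0.2] * 11 + [0.8] * 6)
        labels = np.array([1] * 22 + [0] * 17)
        r = threshold_metrics(probs, labels, cutoff=0.5)
        assert r.sen == pytest.approx(20 / 22)
        assert r.spe == pytest.approx(11 / 17)
        assert r.acc == pytest.approx(31 / 39)
        assert r.ppv == pytest.approx(20 / 26)
        assert r.npv == pytest.approx(11 / 13)
        assert (r.tp + r.fn, r.tn + r.fp) == (22, 17)
        assert r.acc * r.n == pytest.approx(r.tp + r.tn)  # integer accounting

    def test_probs_equal_labels_all_ones(self):
        y = np.array([0, 1, 1, 0, 1])
        r = threshold_metrics(y.astype(float), y)
        assert (r.auc, r.acc, r.sen, r.spe) == (1.0, 1.0, 1.0, 1.0)

    def test_all_below_cutoff_flags_ppv(self):
        r = threshold_metrics(np.full(10, 0.4), np.array([1] * 5 + [0] * 5))
        assert r.sen == 0.0 and r.spe == 1.0
        assert r.ppv is None and "PPV" in r.undefined


class TestBootstrap:
    def test_zero_variance_metric_degenerate_interval(self):
        y = np.array([0, 1] * 10)
        lo, hi, _ = bootstrap_ci(auc, y.astype(float), y, B=200, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_seeded_reproducibility(self, rng):
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        a = bootstrap_ci(auc, probs, labels, B=300, seed=3)
        b = bootstrap_ci(auc, probs, labels, B=300, seed=3)
        assert a == b

    def test_small_b_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_ci(auc, rng.random(20), rng.integers(0, 2, 20), B=100)


class TestPrCurve:
    def test_perfect_ranking_ap_one(self):
        _, ap = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert ap == 1.0

    def test_five_case_hand_oracle(self):
        # descending: (0.9,1) (0.8,0) (0.7,1) (0.6,0) (0.5,1)
        probs = [0.9, 0.8, 0.7, 0.6, 0.5]
        labels = [1, 0, 1, 0, 1]
        # steps at ranks 1,3,5: precision 1/1, 2/3, 3/5; recall +1/3 each
        expected = (1.0 + 2 / 3 + 3 / 5) / 3
        _, ap = pr_curve(probs, labels)
        assert ap == pytest.approx(expected)

    def test_random_scores_ap_near_prevalence(self, rng):
        n, prev = 4000, 0.3
        labels = (rng.random(n) < prev).astype(int)
        _, ap = pr_curve(rng.random(n), labels)
        assert ap == pytest.approx(labels.mean(), abs=0.04)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.5, 0.6], [0, 0])


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit_is_prevalence(self):
        labels = np.array([1] * 6 + [0] * 14)
        dc = decision_curve(labels.astype(float), labels)
        np.testing.assert_allclose(dc.nb_model, labels.mean(), atol=1e-12)
        assert dc.nb_model.max() <= labels.mean() + 1e-12  # NB upper bound

    def test_constant_one_probs_equal_treat_all(self):
        labels = np.array([1] * 5 + [0] * 5)
        dc = decision_curve(np.ones(10), labels)
        np.testing.assert_allclose(dc.nb_model, dc.nb_all, atol=1e-12)
        assert dc.beneficial_intervals == []  # no strict benefit anywhere

    def test_ten_case_hand_arithmetic_at_half(self):
        probs = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.9, 0.3, 0.2, 0.1, 0.6])
        labels = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 1])
        dc = decision_curve(probs, labels, step=0.1)
        i = int(np.argmin(np.abs(dc.thresholds - 0.5)))
        # at p_t=0.5: predicted positive = probs>=0.5 -> TP=4, FP=2
        expected = 4 / 10 - 2 / 10 * (0.5 / 0.5)
        assert dc.nb_model[i] == pytest.approx(expected)

    def test_treat_all_closed_form(self, rng):
        labels = rng.integers(0, 2, 40)
        dc = decision_curve(rng.random(40), labels)
        prev = labels.mean()
        w = dc.thresholds / (1 - dc.thresholds)
        np.testing.assert_allclose(dc.nb_all, prev - (1 - prev) * w, atol=1e-12)
        np.testing.assert_allclose(dc.nb_none, 0.0)

    def test_beneficial_interval_reported_for_good_model(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        probs = np.clip(labels * 0.6 + rng.normal(0.2, 0.15, n), 0.01, 0.99)
        dc = decision_curve(probs, labels)
        assert dc.final_interval is not None
        lo, hi = dc.final_interval
        assert 0 < lo < hi < 1


class TestHanleyMcNeil:
    def test_exact_value_at_half_with_unit_counts(self):
        _, _, v = hanley_mcneil_variance(0.5, 1, 1)
        assert v == pytest.approx(0.25)

    def test_variance_decreases_with_sample_size(self):
        vs = [hanley_mcneil_variance(0.8, n, n)[2] for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(vs, vs[1:]))

    def test_against_monte_carlo_binormal(self, rng):
        """V(0.8, 20, 20) vs the empirical variance of pair-counting AUC."""
        A, n1, n0, reps = 0.8, 20, 20, 50_000
        mu = np.sqrt(2.0) * 1.0  # binormal with d' giving AUC 0.8: Phi(mu/sqrt(2))=0.8
        from scipy.stats import norm

        mu = norm.ppf(A) * np.sqrt(2.0)
        x1 = rng.normal(mu, 1.0, size=(reps, n1))
        x0 = rng.normal(0.0, 1.0, size=(reps, n0))
        wins = (x1[:, :, None] > x0[:, None, :]).mean(axis=(1, 2))
        mc_var = wins.var()
        _, _, v = hanley_mcneil_variance(A, n1, n0)
        assert abs(v - mc_var) / mc_var <= 0.15

    def test_power_behaviour(self):
        small = hanley_mcneil(0.8, 7, 4)
        large = hanley_mcneil(0.8, 25, 14)
        assert 0 < small.power < large.power <= 1.0
        assert small.q1 == pytest.approx(0.8 / 1.2)
        assert small.q2 == pytest.approx(2 * 0.64 / 1.8)

    def test_degenerate_auc_rejected(self):
        with pytest.raises(ValueError):
            hanley_mcneil(1.0, 10, 10)


class TestReconstructConfusion:
    def test_perfect_metrics(self):
        r = reconstruct_confusion(1.00, 1.00, 12, 8)
        assert (r.tp, r.tn, r.acc) == (12, 8, 1.00)

    def test_inconsistent_printed_values_flagged(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(0.43, 0.50, 4, 4)  # 0.43 unreachable with n1=4

    def test_rounding_half_away_from_zero(self):
        # 0.125 rounds to 0.13 under half-away-from-zero
        from dpetfusion.metrics import _round2

        assert _round2(0.125) == 0.13
        assert _round2(0.815) == 0.82


class TestReconstructionRoundTrip:
    """Printing any integer confusion matrix at two decimals and
    reconstructing must recover it among the candidates."""

    from hypothesis import given, settings, strategies as st

    @given(
        n1=st.integers(2, 30),
        n0=st.integers(2, 30),
        tp_frac=st.floats(0, 1),
        tn_frac=st.floats(0, 1),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_round_trip_recovers_cells(self, n1, n0, tp_frac, tn_frac):
        from dpetfusion.metrics import _round2, reconstruct_confusion

        tp = int(round(tp_frac * n1))
        tn = int(round(tn_frac * n0))
        r = reconstruct_confusion(_round2(tp / n1), _round2(tn / n0), n1, n0)
        assert (tp, tn) in r.candidates
        if r.unique:
            assert (r.tp, r.tn) == (tp, tn)


class TestThresholdResponse:
    def test_endpoints(self, rng):
        probs = rng.random(30)
        labels = rng.integers(0, 2, 30)
        tr = threshold_response(probs, labels)
        assert tr.iloc[0]["sensitivity"] == 1.0  # threshold 0: everyone positive
        assert tr.iloc[-1]["specificity"] == 1.0

    def test_density_integrates_to_one(self, rng):
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        dens = probability_density(probs, labels, n_bins=20)
        for cls in (0, 1):
            sub = dens[dens.label == cls]
            integral = (sub["density"] * (sub["bin_high"] - sub["bin_low"])).sum()
            assert integral == pytest.approx(1.0)


class TestBaselineClinicalModel:
    def _clinical(self, rng, n, label=None):
        frame = pd.DataFrame(
            {
                "age": rng.normal(52, 10, n),
                "ki67": rng.uniform(5, 95, n),
                "suvmax": rng.uniform(14, 65, n),
                "cT": rng.integers(1, 5, n),
                "cN": rng.integers(0, 4, n),
                "grade": rng.integers(2, 4, n),
                "regimen": rng.choice(["TCbHP", "PCbHP"], n),
            }
        )
        return frame

    def test_one_hot_encoding_of_regimen(self, rng):
        X = self._clinical(rng, 60)
        y = rng.integers(0, 2, 60)
        model = baseline_clinical_model(X, y, seed=0)
        enc = model.named_steps["pre"].named_transformers_["cat"]
        cats = {tuple(c) for c in enc.categories_}
        assert ("PCbHP", "TCbHP") in cats

    def test_dominant_covariate_perfect_auc(self, rng):
        X = self._clinical(rng, 80)
        y = (X["suvmax"] > X["suvmax"].median()).astype(int).to_numpy()
        model = baseline_clinical_model(X, y, seed=0)
        assert auc(model.predict_proba(X)[:, 1], y) == 1.0

    def test_label_independent_covariates_weak(self, rng):
        X = self._clinical(rng, 200)
        y = rng.integers(0, 2, 200)
        model = baseline_clinical_model(X.iloc[:100], y[:100], seed=0)
        a = auc(model.predict_proba(X.iloc[100:])[:, 1], y[100:])
        assert 0.35 <= a <= 0.65

    def test_unseen_category_raises(self, rng):
        X = self._clinical(rng, 40)
        y = rng.integers(0, 2, 40)
        model = baseline_clinical_model(X, y, seed=0)
        bad = X.copy()
        bad.loc[bad.index[0], "regimen"] = "UNKNOWN"
        with pytest.raises(Exception):
            model.predict_proba(bad)
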