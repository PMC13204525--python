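"""Selection cascade oracles: exact U tests, brute-force mRMR, LASSO recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dpetfusion.radiomics import (
    ExtractionProfile,
    _binned_mi,
    _equal_frequency_bins,
    fit_radiomics_classifier,
    lasso_select,
    mrmr_select,
    run_selection_cascade,
    stability_bootstrap,
    utest_filter,
)


class TestUTestFilter:
    def test_identical_feature_dropped_with_p_one(self, rng):
        X = pd.DataFrame({"const": np.ones(30), "noise": rng.normal(size=30)})
        y = np.array([0, 1] * 15)
        kept, pvals = utest_filter(X, y, alpha=0.05)
        assert "const" not in kept
        assert pvals["const"] == pytest.approx(1.0)

    def test_perfect_separation_matches_exact_enumeration(self):
        """n=10 vs 10, U=0: compare against scipy's exact-method p-value."""
        x = np.concatenate([np.arange(10.0), np.arange(10.0) + 100])
        y = np.array([0] * 10 + [1] * 10)
        X = pd.DataFrame({"f": x})
        kept, pvals = utest_filter(X, y, alpha=1e-3)
        u = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
        exact = stats.mannwhitneyu(
            x[y == 1], x[y == 0], alternative="two-sided", method="exact"
        ).pvalue
        assert u.statistic in (0.0, 100.0)  # complete separation
        assert "f" in kept
        assert pvals["f"] < 1e-3 and exact < 1e-3

    def test_null_type_one_retention_near_alpha(self, rng):
        n, p, alpha = 60, 1000, 0.05
        X = pd.DataFrame(rng.normal(size=(n, p)))
        X.columns = [f"f{i}" for i in range(p)]
        y = rng.permutation([0, 1] * (n // 2))
        kept, _ = utest_filter(X, y, alpha=alpha)
        se = np.sqrt(alpha * (1 - alpha) / p)
        assert abs(len(kept) / p - alpha) <= 3 * se

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=10)})
        with pytest.raises(ValueError):
            utest_filter(X, np.ones(10), alpha=0.05)


class TestMrmr:
    def test_redundant_copy_skipped(self, rng):
        y = rng.integers(0, 2, size=200)
        f1 = y.astype(float) + rng.normal(0, 0.01, 200)
        X = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": rng.normal(size=200)})
        picked = mrmr_select(X, y, m=2)
        assert picked[0] == "f1"
        assert picked[1] == "f3"  # the duplicate is maximally redundant

    def test_exhaustion_returns_permutation(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("abcdef"))
        y = rng.integers(0, 2, 50)
        picked = mrmr_select(X, y, m=6)
        assert sorted(picked) == list("abcdef")

    def test_matches_brute_force_greedy(self, rng):
        """Independent greedy implementation with the same MI estimator."""
        n, p, m, bins = 80, 8, 5, 8
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        X["f1"] += 1.5 * rng.integers(0, 2, n)
        y = rng.integers(0, 2, n)

        binned = [
            _equal_frequency_bins(X[c].to_numpy(), bins) for c in X.columns
        ]
        rel = [_binned_mi(b, y.astype(int), bins, 2) for b in binned]
        chosen, remaining = [], list(range(p))
        while len(chosen) < m:
            best, best_score = None, -np.inf
            for j in remaining:
                red = np.mean([_binned_mi(binned[j], binned[k], bins, bins) for k in chosen]) if chosen else 0.0
                score = rel[j] - red
                if score > best_score:  # strict: first max wins (column order)
                    best, best_score = j, score
            chosen.append(best)
            remaining.remove(best)
        expected = [X.columns[i] for i in chosen]
        assert mrmr_select(X, y, m=m, n_bins=bins) == expected

    def test_row_duplication_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, 40)
        doubled = pd.concat([X, X], ignore_index=True)
        assert mrmr_select(X, y, m=3) == mrmr_select(doubled, np.concatenate([y, y]), m=3)

    def test_invalid_m_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError):
            mrmr_select(X, rng.integers(0, 2, 10), m=0)


class TestLasso:
    def test_planted_model_recovery(self, rng):
        n, p_noise = 300, 48
        informative = rng.normal(size=(n, 2))
        logits = 2.5 * informative[:, 0] - 2.0 * informative[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        X = pd.DataFrame(
            np.column_stack([informative, rng.normal(size=(n, p_noise))]),
            columns=[f"f{i}" for i in range(p_noise + 2)],
        )
        names, lam, coefs = lasso_select(X, y, seed=0)
        assert "f0" in names and "f1" in names
        false_pos = [c for c in names if c not in ("f0", "f1")]
        assert len(false_pos) <= 3
        assert np.sign(coefs["f0"]) > 0 and np.sign(coefs["f1"]) < 0

    def test_zero_variance_column_gets_zero_coefficient(self, rng):
        X = pd.DataFrame({"signal": rng.normal(size=100), "flat": np.zeros(100)})
        y = (X["signal"] > 0).astype(int).to_numpy()
        names, _, coefs = lasso_select(X, y, seed=1)
        assert "flat" not in names

    def test_infinite_penalty_empty_selection(self, rng):
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, 60)
        model = LogisticRegression(l1_ratio=1.0, C=1e-8, solver="liblinear").fit(X, y)
        assert np.all(model.coef_ == 0.0)


class TestClassifiers:
    @pytest.mark.parametrize("algo", ["LR", "RF", "XGB", "KNN", "GNB"])
    def test_separable_toy_all_algorithms_perfect(self, algo, rng):
        n = 40
        y = np.array([0, 1] * (n // 2))
        Z = np.column_stack([y + rng.normal(0, 0.01, n), rng.normal(size=n)])
        clf = fit_radiomics_classifier(Z, y, ["a", "b"], algo=algo, seed=0)
        from dpetfusion.metrics import auc

        assert auc(clf.predict_proba(Z), y) == 1.0

    def test_label_permutation_gives_chance_cv_auc(self, rng):
        n = 80
        Z = rng.normal(size=(n, 5))
        y = rng.permutation([0, 1] * (n // 2))
        clf = fit_radiomics_classifier(Z, y, list("abcde"), algo="LR", seed=0)
        assert 0.35 <= clf.cv_auc <= 0.65

    def test_same_seed_same_hyperparameters(self, rng):
        Z = rng.normal(size=(60, 4))
        y = rng.integers(0, 2, 60)
        a = fit_radiomics_classifier(Z, y, list("abcd"), algo="RF", seed=5)
        b = fit_radiomics_classifier(Z, y, list("abcd"), algo="RF", seed=5)
        assert a.best_params == b.best_params


class TestCascade:
    def test_stage_nesting(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 40)), columns=[f"f{i}" for i in range(40)])
        X["f0"] += 2.0 * y
        X["f1"] -= 1.5 * y
        sel = run_selection_cascade(X, y, m_mrmr=10, seed=0)
        assert set(sel.post_lasso) <= set(sel.post_mrmr) <= set(sel.post_utest)
        assert sel.lasso_lambda > 0

    def test_reproducible_given_seed(self, rng):
        n = 60
        y = rng.integers(0, 2, n)
        X = pd.DataFrame(rng.normal(size=(n, 30)))
        X.columns = [f"f{i}" for i in range(30)]
        X["f3"] = X["f3"] + y
        a = run_selection_cascade(X, y, seed=7)
        b = run_selection_cascade(X, y, seed=7)
        assert a.post_lasso == b.post_lasso and a.lasso_lambda == b.lasso_lambda


class TestStabilityBootstrap:
    def test_dominant_signal_always_reselected(self, rng):
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"f{i}" for i in range(10)])
        X["label_copy"] = y + rng.normal(0, 0.01, n)
        freq, redraws = stability_bootstrap(X, y, B=50, seed=0, m_mrmr=5)
        assert freq["label_copy"] >= 0.98
        assert redraws == 0

    def test_pure_noise_low_max_frequency(self, rng):
        n = 60
        y = rng.permutation([0, 1] * (n // 2))
        X = pd.DataFrame(rng.normal(size=(n, 25)), columns=[f"f{i}" for i in range(25)])
        freq, _ = stability_bootstrap(X, y, B=50, seed=0, m_mrmr=5)
        assert freq.max() <= 0.5  # no noise feature is reselected persistently
        assert ((freq >= 0) & (freq <= 1)).all()

    def test_b_floor_enforced(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        X.columns = list("abc")
        with pytest.raises(ValueError):
            stability_bootstrap(X, rng.integers(0, 2, 20), B=10)


def test_profile_counts():
    assert ExtractionProfile().n_features_per_region == 1688
    assert len(ExtractionProfile().image_names) == 18
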