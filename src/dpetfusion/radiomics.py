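"""Handcrafted radiomics branch: extraction, selection cascade, classifiers.

The default extraction profile yields exactly 1688 named features per
region — 14 3D-shape + 93 intensity/texture on the original image, plus
93 texture features on each of 17 derived images (8 stationary-wavelet
sub-bands, 5 Laplacian-of-Gaussian scales, 4 pointwise transforms). Over
the whole ROI and the two metabolic habitats this gives 5064 columns.

Selection is the three-stage cascade: two-sided Mann-Whitney U filter,
greedy mRMR (difference criterion on binned mutual information), then
L1-penalized logistic regression with lambda chosen by stratified 5-fold
CV. All stages fit on training rows only; transforms are frozen and applied
unchanged to test partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from dpetfusion.filters import default_image_names, image_bank
from dpetfusion.habitats import HabitatMap
from dpetfusion.io import RoiMask, Volume, crop_with_margin
from dpetfusion.texture import (
    TEXTURE_CLASS_SIZES,
    shape3d_features,
    texture_feature_vector,
)

REGIONS = ("whole", "high", "low")


@dataclass(frozen=True)
class ExtractionProfile:
    """Which images and settings the per-region feature bank uses.

    The default (18 images, 32 bins) gives 14 + 18*93 = 1688 features per
    region. ``compact()`` is a 5-image profile used for large simulation
    studies where extraction cost dominates.
    """

    image_names: tuple[str, ...] = tuple(default_image_names())
    n_bins: int = 32
    crop_margin: int = 4  # context voxels so filters see the tumor rim

    @property
    def n_features_per_region(self) -> int:
        return 14 + len(self.image_names) * sum(TEXTURE_CLASS_SIZES.values())

    @classmethod
    def compact(cls) -> "ExtractionProfile":
        return cls(
            image_names=("original", "wavelet-HHH", "log-sigma-2mm"),
            n_bins=16,
        )


def extract_region_features(
    volume: Volume, mask: RoiMask, profile: ExtractionProfile = ExtractionProfile()
) -> dict[str, float]:
    """All named features of one region (default profile: exactly 1688)."""
    if mask.n_foreground == 0:
        raise ValueError("empty region")
    cvol, cmask = crop_with_margin(volume, mask, profile.crop_margin)
    voxel_volume = float(np.prod(cvol.spacing))
    out: dict[str, float] = {}
    for name, val in shape3d_features(cmask.data, cmask.spacing).items():
        out[f"original|shape|{name}"] = val
    bank = image_bank(cvol.data, cvol.spacing, list(profile.image_names))
    for img_name, img in bank.items():
        for key, val in texture_feature_vector(
            img, cmask.data, profile.n_bins, voxel_volume
        ).items():
            out[f"{img_name}|{key}"] = val
    return out


def region_masks(mask: RoiMask, habitat_map: HabitatMap) -> dict[str, RoiMask | None]:
    """Whole-ROI plus high-/low-uptake habitat masks (None when degenerate)."""
    out: dict[str, RoiMask | None] = {"whole": mask}
    for which in ("high", "low"):
        sub = habitat_map.region_mask(which)
        if habitat_map.degenerate_flag or not sub.any():
            out[which] = None
        else:
            out[which] = RoiMask(sub, mask.spacing, mask.origin)
    return out


def case_feature_vector(
    volume: Volume,
    mask: RoiMask,
    habitat_map: HabitatMap,
    profile: ExtractionProfile = ExtractionProfile(),
) -> tuple[dict[str, float], list[str]]:
    """Concatenated whole/high/low feature vector for one case.

    Returns the named vector plus the list of region tags whose features
    are missing (degenerate habitats); missing entries are NaN and are
    median-imputed at table level.
    """
    masks = region_masks(mask, habitat_map)
    out: dict[str, float] = {}
    missing: list[str] = []
    for region in REGIONS:
        rmask = masks[region]
        if rmask is None or rmask.n_foreground == 0:
            missing.append(region)
            template = extract_region_features(volume, mask, profile)
            for key in template:
                out[f"{region}|{key}"] = np.nan
            continue
        for key, val in extract_region_features(volume, rmask, profile).items():
            out[f"{region}|{key}"] = val
    return out, missing


def build_feature_table(
    case_vectors: dict[str, dict[str, float]],
    labels: dict[str, int],
) -> pd.DataFrame:
    """Cases x features table with labels attached and NaNs median-imputed.

    Degenerate-region imputation uses column medians over the table; a
    provenance column ``_imputed_regions`` records affected cases.
    """
    frame = pd.DataFrame.from_dict(case_vectors, orient="index")
    frame.index.name = "case_id"
    medians = frame.median(axis=0)
    frame = frame.fillna(medians).fillna(0.0)
    frame["label"] = pd.Series(labels)
    return frame


def split_features_labels(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    meta = [c for c in ("label", "_imputed_regions") if c in table.columns]
    return table.drop(columns=meta), table["label"].to_numpy()


# ---------------------------------------------------------------------------
# selection cascade
# ---------------------------------------------------------------------------


@dataclass
class SelectedFeatureSet:
    """Stage-by-stage survivors of the U-test -> mRMR -> LASSO cascade."""

    post_utest: list[str]
    post_mrmr: list[str]
    post_lasso: list[str]
    lasso_lambda: float
    coefficients: dict[str, float]
    scaler_mean: pd.Series
    scaler_std: pd.Series

    def transform(self, X: pd.DataFrame, stage: str = "post_lasso") -> np.ndarray:
        cols = getattr(self, stage)
        Z = (X[cols] - self.scaler_mean[cols]) / self.scaler_std[cols]
        return Z.to_numpy()


def utest_filter(
    X: pd.DataFrame, y: np.ndarray, alpha: float = 0.05
) -> tuple[list[str], pd.Series]:
    """Two-sided Mann-Whitney filter: keep features with p < alpha.

    Returns the retained column names and the per-feature p-values
    (normal approximation with tie correction).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes for the U test")
    a = X.to_numpy()[y == 1]
    b = X.to_numpy()[y == 0]
    res = stats.mannwhitneyu(a, b, alternative="two-sided", axis=0, method="asymptotic")
    pvals = pd.Series(res.pvalue, index=X.columns)
    # constant features: mannwhitneyu reports p=1 via tie correction (nan-safe)
    pvals = pvals.fillna(1.0)
    kept = list(pvals.index[pvals < alpha])
    return kept, pvals


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def _binned_mi(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_select(
    X: pd.DataFrame, y: np.ndarray, m: int = 30, n_bins: int = 8,
    criterion: str = "difference",
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance selection.

    Mutual information is estimated on equal-frequency binned features
    (labels used as-is). The default criterion maximizes
    relevance - mean redundancy; ``criterion="quotient"`` maximizes their
    ratio instead. Ties break by column order.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if criterion not in ("difference", "quotient"):
        raise ValueError("criterion must be 'difference' or 'quotient'")
    cols = list(X.columns)
    m = min(m, len(cols))
    y = np.asarray(y).astype(int)
    binned = np.stack(
        [_equal_frequency_bins(X[c].to_numpy().astype(float), n_bins) for c in cols]
    )
    n_lab = int(y.max()) + 1
    relevance = np.array([_binned_mi(b, y, n_bins, n_lab) for b in binned])
    selected: list[int] = []
    redundancy = np.zeros(len(cols))
    remaining = list(range(len(cols)))
    for _ in range(m):
        if selected:
            mean_red = redundancy[remaining] / len(selected)
        else:
            mean_red = np.zeros(len(remaining))
        if criterion == "difference":
            scores = relevance[remaining] - mean_red
        else:
            scores = relevance[remaining] / np.maximum(mean_red, 1e-12)
        best = remaining[int(np.argmax(scores))]  # argmax takes first max: column order
        selected.append(best)
        remaining.remove(best)
        for j in remaining:
            redundancy[j] += _binned_mi(binned[best], binned[j], n_bins, n_bins)
    return [cols[i] for i in selected]


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 40,
    rule: str = "1se",
) -> tuple[list[str], float, dict[str, float]]:
    """L1-logistic selection: lambda by stratified CV binomial deviance.

    ``rule="1se"`` (default) picks the sparsest lambda whose mean CV
    deviance is within one standard error of the minimum — the standard
    guard against the over-selection of plain deviance minimization;
    ``rule="min"`` takes the minimizer itself. Features must already be
    z-scored (training statistics). Returns the nonzero-coefficient feature
    names, lambda*, and the coefficients.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(y)
    Xa = X.to_numpy()
    n = len(y)
    lambdas = np.logspace(-3, 1, n_lambdas)  # lambda = 1 / (C * n)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_dev = []
    for tr, va in skf.split(Xa, y):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate CV fold with a single class")
        dev_k = np.zeros(n_lambdas)
        for k, lam in enumerate(lambdas):
            model = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear",
                max_iter=2000, random_state=seed,
            )
            model.fit(Xa[tr], y[tr])
            p = np.clip(model.predict_proba(Xa[va])[:, 1], 1e-12, 1 - 1e-12)
            dev_k[k] = -2.0 * (
                y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p)
            ).mean()
        fold_dev.append(dev_k)
    fold_dev = np.asarray(fold_dev)
    mean_dev = fold_dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    if rule == "1se":
        se = fold_dev[:, best].std(ddof=1) / np.sqrt(folds)
        within = np.nonzero(mean_dev <= mean_dev[best] + se)[0]
        best = int(within.max())  # largest lambda (sparsest) within one SE
    lam = float(lambdas[best])
    final = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (lam * n), solver="liblinear",
        max_iter=2000, random_state=seed,
    )
    final.fit(Xa, y)
    coefs = final.coef_.ravel()
    nonzero = np.abs(coefs) > 1e-10
    names = [c for c, nz in zip(X.columns, nonzero) if nz]
    return names, lam, {c: float(w) for c, w in zip(X.columns, coefs) if abs(w) > 1e-10}


def run_selection_cascade(
    X: pd.DataFrame,
    y: np.ndarray,
    alpha: float = 0.05,
    m_mrmr: int = 30,
    folds: int = 5,
    seed: int = 0,
) -> SelectedFeatureSet:
    """Full U-test -> mRMR -> LASSO cascade on training rows only."""
    kept, _ = utest_filter(X, y, alpha)
    if len(kept) < 2:
        # fall back to the least-insignificant features so the pipeline
        # stays runnable on null data (selection quality is then nominal)
        _, pvals = utest_filter(X, y, alpha=1.1)
        kept = list(pvals.sort_values().index[: max(2, m_mrmr // 3)])
    mean = X[kept].mean()
    std = X[kept].std(ddof=0).replace(0.0, 1.0)
    Z = (X[kept] - mean) / std
    mrmr_cols = mrmr_select(Z, y, m=m_mrmr)
    lasso_cols, lam, coefs = lasso_select(Z[mrmr_cols], y, folds=folds, seed=seed)
    if not lasso_cols:  # full shrinkage on null data: keep the top mRMR feature
        lasso_cols = mrmr_cols[:1]
        coefs = {mrmr_cols[0]: 0.0}
    return SelectedFeatureSet(
        post_utest=kept,
        post_mrmr=mrmr_cols,
        post_lasso=lasso_cols,
        lasso_lambda=lam,
        coefficients=coefs,
        scaler_mean=mean,
        scaler_std=std,
    )


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

CLASSIFIER_NAMES = ("LR", "RF", "XGB", "KNN", "GNB")


def _classifier_and_grid(algo: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from xgboost import XGBClassifier

    if algo == "LR":
        return (
            LogisticRegression(max_iter=4000, solver="liblinear", random_state=seed),
            {"C": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.0, 1.0]},
        )
    if algo == "RF":
        return (
            RandomForestClassifier(random_state=seed),
            {"n_estimators": [100, 300], "max_depth": [None, 4]},
        )
    if algo == "XGB":
        return (
            XGBClassifier(
                eval_metric="logloss",
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            ),
            {"n_estimators": [100, 200], "max_depth": [2, 3], "learning_rate": [0.1]},
        )
    if algo == "KNN":
        return (KNeighborsClassifier(), {"n_neighbors": [3, 5, 9], "weights": ["uniform", "distance"]})
    if algo == "GNB":
        return (GaussianNB(), {"var_smoothing": [1e-9, 1e-7]})
    raise ValueError(f"unknown algorithm {algo!r}")


@dataclass
class FittedClassifier:
    algo: str
    model: object
    best_params: dict
    cv_auc: float
    feature_names: list[str]

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(Z)[:, 1]


def fit_radiomics_classifier(
    Z: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    algo: str = "LR",
    folds: int = 5,
    seed: int = 0,
) -> FittedClassifier:
    """Grid-search one of the five algorithms by stratified-CV AUC, refit on all rows."""
    from sklearn.model_selection import GridSearchCV, StratifiedKFold

    base, grid = _classifier_and_grid(algo, seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(base, grid, scoring="roc_auc", cv=skf, n_jobs=1, refit=True)
    gs.fit(Z, y)
    return FittedClassifier(
        algo=algo,
        model=gs.best_estimator_,
        best_params=dict(gs.best_params_),
        cv_auc=float(gs.best_score_),
        feature_names=list(feature_names),
    )


def out_of_fold_probabilities(
    Z: np.ndarray, y: np.ndarray, algo: str, folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Out-of-fold probabilities of the (grid-searched per fold) classifier.

    Used as leakage-free stacking inputs for training cases.
    """
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(y)
    oof = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, va in skf.split(Z, y):
        fitted = fit_radiomics_classifier(Z[tr], y[tr], [], algo=algo, folds=min(folds, 3), seed=seed)
        oof[va] = fitted.predict_proba(Z[va])
    return oof


# ---------------------------------------------------------------------------
# stability bootstrap
# ---------------------------------------------------------------------------


def stability_bootstrap(
    X: pd.DataFrame,
    y: np.ndarray,
    B: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    m_mrmr: int = 30,
) -> tuple[pd.Series, int]:
    """Selection frequency of each final feature over B bootstrap reruns.

    Resamples training rows with replacement; single-class resamples are
    redrawn (and counted). Returns frequencies for every feature ever
    selected and the number of redraws.
    """
    if B < 50:
        raise ValueError("need B >= 50 bootstrap replicates")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    n = len(y)
    counts: dict[str, int] = {}
    redraws = 0
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
            redraws += 1
        Xb = X.iloc[idx].reset_index(drop=True)
        sel = run_selection_cascade(Xb, y[idx], alpha=alpha, m_mrmr=m_mrmr, seed=seed + b)
        for c in sel.post_lasso:
            counts[c] = counts.get(c, 0) + 1
    freq = pd.Series({c: v / B for c, v in counts.items()}).sort_values(ascending=False)
    return freq, redraws
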