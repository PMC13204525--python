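"""Quantitative reporting: fixed-cutoff metrics, AUC + bootstrap CIs, PR,
decision-curve analysis, Hanley-McNeil variance/power, threshold-response
curves, confusion-matrix reconstruction from printed two-decimal metrics,
and the clinical baseline model.

AUC is the Mann-Whitney pair-counting estimator (ties count 1/2); headline
metrics use a fixed probability cutoff of 0.5; bootstrap intervals are
class-stratified percentile intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


# ---------------------------------------------------------------------------
# AUC and fixed-cutoff metrics
# ---------------------------------------------------------------------------


def auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney pair-counting AUC; ties contribute 1/2."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes for AUC")
    ranks = sps.rankdata(probs)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_points(probs: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, probs)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class MetricReport:
    """Point metrics at a cutoff with optional bootstrap 95% CIs."""

    auc: float
    acc: float
    sen: float
    spe: float
    ppv: float | None
    npv: float | None
    cutoff: float
    n: int
    n1: int
    n0: int
    tp: int
    tn: int
    fp: int
    fn: int
    undefined: list[str] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "AUC": self.auc, "ACC": self.acc, "SEN": self.sen, "SPE": self.spe,
            "PPV": self.ppv, "NPV": self.npv, "cutoff": self.cutoff,
            "n": self.n, "n1": self.n1, "n0": self.n0,
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
        }
        for name, (lo, hi) in self.ci.items():
            out[f"{name}_ci"] = (lo, hi)
        return out


def threshold_metrics(probs: np.ndarray, labels: np.ndarray, cutoff: float = 0.5) -> MetricReport:
    """SEN/SPE/ACC/PPV/NPV at a fixed cutoff; undefined ratios are flagged."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if probs.size == 0:
        raise ValueError("empty input")
    pred = (probs >= cutoff).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n1, n0 = tp + fn, tn + fp
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes")
    undefined = []
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    npv = tn / (tn + fn) if (tn + fn) > 0 else None
    if ppv is None:
        undefined.append("PPV")
    if npv is None:
        undefined.append("NPV")
    return MetricReport(
        auc=auc(probs, labels),
        acc=(tp + tn) / (n1 + n0),
        sen=tp / n1,
        spe=tn / n0,
        ppv=ppv,
        npv=npv,
        cutoff=cutoff,
        n=n1 + n0,
        n1=n1,
        n0=n0,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def bootstrap_ci(
    metric,
    probs: np.ndarray,
    labels: np.ndarray,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float, int]:
    """Class-stratified percentile bootstrap interval for ``metric(probs, labels)``.

    Degenerate or metric-undefined resamples are redrawn (counted; flagged
    by raising if more than 10% of draws fail).
    """
    if B < 200:
        raise ValueError("need B >= 200")
    rng = np.random.default_rng(seed)
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    idx1 = np.nonzero(labels == 1)[0]
    idx0 = np.nonzero(labels == 0)[0]
    values = np.empty(B)
    failures = 0
    for b in range(B):
        for _ in range(50):
            take = np.concatenate(
                [rng.choice(idx1, size=len(idx1)), rng.choice(idx0, size=len(idx0))]
            )
            try:
                values[b] = metric(probs[take], labels[take])
                break
            except (ValueError, ZeroDivisionError):
                failures += 1
        else:
            raise RuntimeError("metric undefined on too many bootstrap resamples")
    if failures > 0.1 * B:
        raise RuntimeError(f"metric undefined on {failures} of {B} resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi), failures


def report_with_cis(
    probs: np.ndarray,
    labels: np.ndarray,
    cutoff: float = 0.5,
    B: int = 2000,
    seed: int = 0,
) -> MetricReport:
    """Threshold metrics plus bootstrap CIs for AUC/ACC/SEN/SPE."""
    rep = threshold_metrics(probs, labels, cutoff)

    def metric_fn(name):
        if name == "AUC":
            return auc
        def fn(p, y):
            r = threshold_metrics(p, y, cutoff)
            return {"ACC": r.acc, "SEN": r.sen, "SPE": r.spe}[name]
        return fn

    for name in ("AUC", "ACC", "SEN", "SPE"):
        lo, hi, _ = bootstrap_ci(metric_fn(name), probs, labels, B=B, seed=seed)
        rep.ci[name] = (lo, hi)
    return rep


# ---------------------------------------------------------------------------
# precision-recall
# ---------------------------------------------------------------------------


def pr_curve(probs: np.ndarray, labels: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Precision-recall points and step-interpolated average precision.

    AP = sum over descending-score steps of precision x recall increment,
    with explicit (recall 0) and (recall 1) endpoints in the point list.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    if n1 == 0:
        raise ValueError("no positives")
    order = np.argsort(-probs, kind="stable")
    y = labels[order]
    p_sorted = probs[order]
    tp = np.cumsum(y)
    k = np.arange(1, len(y) + 1)
    # evaluate only at distinct-threshold boundaries
    boundary = np.append(p_sorted[1:] != p_sorted[:-1], True)
    precision = tp[boundary] / k[boundary]
    recall = tp[boundary] / n1
    ap = 0.0
    prev_recall = 0.0
    for prec, rec in zip(precision, recall):
        ap += prec * (rec - prev_recall)
        prev_recall = rec
    frame = pd.DataFrame(
        {
            "recall": np.concatenate([[0.0], recall]),
            "precision": np.concatenate([[1.0], precision]),
            "threshold": np.concatenate([[np.inf], p_sorted[boundary]]),
        }
    )
    return frame, float(ap)


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    beneficial_intervals: list[tuple[float, float]]

    @property
    def final_interval(self) -> tuple[float, float] | None:
        """The longest ('final continuous') beneficial threshold run."""
        if not self.beneficial_intervals:
            return None
        return max(self.beneficial_intervals, key=lambda iv: iv[1] - iv[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "nb_model": self.nb_model,
                "nb_treat_all": self.nb_all,
                "nb_treat_none": self.nb_none,
            }
        )


def decision_curve(probs: np.ndarray, labels: np.ndarray, step: float = 0.01) -> DecisionCurve:
    """Net benefit NB(p_t) = TP/n - FP/n * p_t/(1-p_t) versus both references.

    Beneficial intervals are maximal runs where the model strictly exceeds
    treat-all and treat-none; p_t = 1 is excluded from the grid.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    prevalence = labels.mean()
    thresholds = np.arange(step, 1.0, step)
    nb_model = np.empty_like(thresholds)
    nb_all = np.empty_like(thresholds)
    for i, pt in enumerate(thresholds):
        pred = probs >= pt
        tp = float((pred & (labels == 1)).sum())
        fp = float((pred & (labels == 0)).sum())
        w = pt / (1.0 - pt)
        nb_model[i] = tp / n - fp / n * w
        nb_all[i] = prevalence - (1.0 - prevalence) * w
    nb_none = np.zeros_like(thresholds)
    better = (nb_model > nb_all) & (nb_model > nb_none)
    intervals = []
    start = None
    for i, flag in enumerate(better):
        if flag and start is None:
            start = thresholds[i]
        elif not flag and start is not None:
            intervals.append((float(start), float(thresholds[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(start), float(thresholds[-1])))
    return DecisionCurve(thresholds, nb_model, nb_all, nb_none, intervals)


# ---------------------------------------------------------------------------
# Hanley-McNeil variance and power
# ---------------------------------------------------------------------------


@dataclass
class PowerReport:
    auc: float
    n1: int
    n0: int
    alpha: float
    q1: float
    q2: float
    variance: float
    power: float


def hanley_mcneil_variance(A: float, n1: int, n0: int) -> tuple[float, float, float]:
    """V(A) = [A(1-A) + (n1-1)(Q1-A^2) + (n0-1)(Q2-A^2)] / (n1 n0)."""
    q1 = A / (2.0 - A)
    q2 = 2.0 * A**2 / (1.0 + A)
    v = (A * (1 - A) + (n1 - 1) * (q1 - A**2) + (n0 - 1) * (q2 - A**2)) / (n1 * n0)
    return q1, q2, v


def hanley_mcneil(A: float, n1: int, n0: int, alpha: float = 0.05) -> PowerReport:
    """Hanley-McNeil AUC variance and power for the two-sided test of A = 0.5.

    The critical value uses the null variance (at A = 0.5) and the
    alternative uses V(A); normal approximation throughout.
    """
    if not 0 < A < 1:
        raise ValueError("need 0 < A < 1")
    if n1 < 1 or n0 < 1:
        raise ValueError("need n1, n0 >= 1")
    q1, q2, v = hanley_mcneil_variance(A, n1, n0)
    _, _, v0 = hanley_mcneil_variance(0.5, n1, n0)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    se0, se1 = np.sqrt(v0), np.sqrt(v)
    shift = abs(A - 0.5)
    power = float(
        sps.norm.cdf((shift - z * se0) / se1) + sps.norm.cdf((-shift - z * se0) / se1)
    )
    return PowerReport(A, n1, n0, alpha, q1, q2, float(v), power)


# ---------------------------------------------------------------------------
# confusion-matrix reconstruction from printed metrics
# ---------------------------------------------------------------------------


def _round2(x: float) -> float:
    """Round half away from zero at 2 decimals (printed-table convention)."""
    return float(np.floor(x * 100 + 0.5) / 100)


@dataclass
class ReconstructedConfusion:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    ppv: float | None
    npv: float | None
    unique: bool
    candidates: list[tuple[int, int]]


def reconstruct_confusion(
    sen_printed: float, spe_printed: float, n1: int, n0: int
) -> ReconstructedConfusion:
    """Recover integer (TP, TN) from two-decimal printed SEN/SPE.

    Searches all integer cell counts whose ratios round to the printed
    values; raises if none is consistent, flags ambiguity if several are.
    Derived ACC/PPV/NPV are rounded to two decimals the same way.
    """
    tps = [tp for tp in range(n1 + 1) if _round2(tp / n1) == round(sen_printed, 2)]
    tns = [tn for tn in range(n0 + 1) if _round2(tn / n0) == round(spe_printed, 2)]
    candidates = [(tp, tn) for tp in tps for tn in tns]
    if not candidates:
        raise ValueError(
            f"no integer confusion matrix matches SEN={sen_printed}, SPE={spe_printed} "
            f"with n1={n1}, n0={n0}"
        )
    tp, tn = candidates[0]
    fp, fn = n0 - tn, n1 - tp
    ppv = _round2(tp / (tp + fp)) if tp + fp > 0 else None
    npv = _round2(tn / (tn + fn)) if tn + fn > 0 else None
    return ReconstructedConfusion(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        acc=_round2((tp + tn) / (n1 + n0)),
        ppv=ppv,
        npv=npv,
        unique=len(candidates) == 1,
        candidates=candidates,
    )


# ---------------------------------------------------------------------------
# threshold-response curves and probability densities
# ---------------------------------------------------------------------------


def threshold_response(probs: np.ndarray, labels: np.ndarray, step: float = 0.01) -> pd.DataFrame:
    """Sensitivity and specificity across the full threshold range."""
    labels = np.asarray(labels).astype(int)
    probs = np.asarray(probs, dtype=np.float64)
    thresholds = np.arange(0.0, 1.0 + step / 2, step)
    sen = [(probs[labels == 1] >= t).mean() for t in thresholds]
    spe = [(probs[labels == 0] < t).mean() for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "sensitivity": sen, "specificity": spe})


def probability_density(probs: np.ndarray, labels: np.ndarray, n_bins: int = 20) -> pd.DataFrame:
    """Per-class probability histograms normalized to integrate to 1."""
    labels = np.asarray(labels).astype(int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for cls in (0, 1):
        hist, _ = np.histogram(probs[labels == cls], bins=edges, density=True)
        for lo, hi, d in zip(edges[:-1], edges[1:], hist):
            rows.append({"label": cls, "bin_low": lo, "bin_high": hi, "density": d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical baseline model
# ---------------------------------------------------------------------------

CONTINUOUS_COVARIATES = ("age", "ki67", "suvmax")
CATEGORICAL_COVARIATES = ("cT", "cN", "grade", "regimen")
# declared vocabularies: every level encodes even if absent from training;
# values outside these vocabularies raise at transform time
CATEGORY_LEVELS = {
    "cT": [1, 2, 3, 4],
    "cN": [0, 1, 2, 3],
    "grade": [2, 3],
    "regimen": ["PCbHP", "TCbHP"],
}


def baseline_clinical_model(
    clinical: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    folds: int = 5,
):
    """Clinical-covariate logistic baseline with the standard grid.

    Continuous covariates are z-scored, categoricals one-hot encoded;
    regularization type/strength, elastic-net ratio, solver and class
    weighting are grid-searched by stratified-CV AUC and the winner refit
    on the full training data. Unseen categories at inference raise.
    """
    from sklearn.compose import ColumnTransformer
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import OneHotEncoder, StandardScaler

    X = clinical[list(CONTINUOUS_COVARIATES) + list(CATEGORICAL_COVARIATES)]
    pre = ColumnTransformer(
        [
            ("cont", StandardScaler(), list(CONTINUOUS_COVARIATES)),
            (
                "cat",
                OneHotEncoder(
                    categories=[CATEGORY_LEVELS[c] for c in CATEGORICAL_COVARIATES],
                    handle_unknown="error",
                ),
                list(CATEGORICAL_COVARIATES),
            ),
        ]
    )
    pipe = Pipeline([("pre", pre), ("lr", LogisticRegression(max_iter=5000, random_state=seed))])
    grid = [
        {   # ridge
            "lr__l1_ratio": [0.0],
            "lr__C": [0.01, 0.1, 1.0, 10.0],
            "lr__solver": ["lbfgs", "liblinear"],
            "lr__class_weight": [None, "balanced"],
        },
        {   # lasso
            "lr__l1_ratio": [1.0],
            "lr__C": [0.01, 0.1, 1.0, 10.0],
            "lr__solver": ["liblinear"],
            "lr__class_weight": [None, "balanced"],
        },
        {   # elastic net
            "lr__l1_ratio": [0.2, 0.5, 0.8],
            "lr__C": [0.1, 1.0],
            "lr__solver": ["saga"],
            "lr__class_weight": [None, "balanced"],
        },
    ]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(pipe, grid, scoring="roc_auc", cv=skf, n_jobs=1)
    gs.fit(X, np.asarray(labels).astype(int))
    return gs.best_estimator_
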