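"""Interpretability: 3D Grad-CAM, exact linear SHAP, feature correlations.

Attributions for linear models are computed on the link (log-odds) scale,
where they are exactly additive: base value + sum of contributions equals
the model's link output at machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from dpetfusion.nn.autograd import Tensor
from dpetfusion.nn.models import INPUT_SHAPE, ResNet3DSmall
from dpetfusion.nn.train import _model_inputs


@dataclass
class AttentionMap:
    """Per-voxel relevance in [0, 1] at input resolution."""

    data: np.ndarray
    degenerate: bool
    source: str = "last_conv_stage"


def gradcam3d(model: ResNet3DSmall, grid: np.ndarray, stage: int | None = None) -> AttentionMap:
    """Gradient-weighted class activation map of a residual stage.

    By default the deepest stage whose activation keeps spatial extent
    >= 4 voxels is used (the very last stage of the compact model pools to
    a single voxel, which carries no localization). Channel weights are
    global-average gradients of the logit; the weighted activation sum is
    rectified, trilinearly upsampled to 64^3 and max-normalized. All-zero
    gradients yield a degenerate all-zero map.
    """
    model.set_training(False)
    X = grid[None, None].astype(np.float32)
    xt = Tensor(_model_inputs(model, X))
    logit = model(xt, keep_cam=True)
    acts = model._stage_activations
    if stage is None:
        candidates = [a for a in acts if min(a.shape[2:]) >= 4]
        act = candidates[-1] if candidates else acts[0]
    else:
        act = acts[stage]
    logit.backward(np.ones_like(logit.data))
    grads = act.grad[0]  # (C, d, h, w)
    weights = grads.mean(axis=(1, 2, 3))
    cam = np.maximum((weights[:, None, None, None] * act.data[0]).sum(axis=0), 0.0)
    peak = cam.max()
    if peak <= 0:
        return AttentionMap(np.zeros(INPUT_SHAPE, dtype=np.float64), degenerate=True)
    factors = [t / s for t, s in zip(INPUT_SHAPE, cam.shape)]
    up = ndimage.zoom(cam.astype(np.float64), factors, order=1, mode="nearest", grid_mode=True)
    up = np.clip(up, 0.0, None)
    return AttentionMap(up / up.max(), degenerate=False)


@dataclass
class AttributionSet:
    """Signed per-feature contributions on the link scale, plus base value."""

    contributions: pd.DataFrame  # cases x features
    base_value: float

    def link_outputs(self) -> np.ndarray:
        return self.base_value + self.contributions.to_numpy().sum(axis=1)


def linear_shap(coefficients: dict[str, float], intercept: float, X: pd.DataFrame,
                background_mean: pd.Series) -> AttributionSet:
    """Exact SHAP values of a linear model: coef_j * (x_j - mean_j).

    ``background_mean`` must be the training feature means; additivity to
    the model's log-odds holds exactly.
    """
    names = list(coefficients)
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing}")
    coef = np.array([coefficients[n] for n in names])
    contrib = (X[names].to_numpy() - background_mean[names].to_numpy()) * coef
    base = float(intercept + coef @ background_mean[names].to_numpy())
    return AttributionSet(pd.DataFrame(contrib, index=X.index, columns=names), base)


def linear_shap_from_sklearn(model, X: pd.DataFrame, background_mean: pd.Series) -> AttributionSet:
    coefs = dict(zip(X.columns, model.coef_.ravel()))
    return linear_shap(coefs, float(model.intercept_[0]), X, background_mean)


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of the selected features (diagonal exactly 1).

    Zero-variance features get NaN rows/columns (flagged missing).
    """
    if features.shape[1] < 2 or features.shape[0] < 3:
        raise ValueError("need >= 2 features and >= 3 cases")
    X = features.to_numpy(dtype=np.float64)
    std = X.std(axis=0)
    corr = np.full((X.shape[1], X.shape[1]), np.nan)
    ok = std > 0
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=features.columns, columns=features.columns)
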