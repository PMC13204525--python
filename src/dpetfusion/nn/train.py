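"""Tensorization and CPU training for the deep branch.

Model selection follows the branch protocol: candidate configurations are
compared by mean out-of-fold AUC under stratified five-fold CV inside the
training set only; the winner is retrained on all training cases. The
out-of-fold probabilities of the winning configuration are retained as
leakage-free inputs for the stacking meta-learner. Held-out partitions are
never touched during selection, early stopping or scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from dpetfusion.io import RoiMask, Volume, crop_with_margin, resample_to_shape
from dpetfusion.nn.autograd import Tensor, bce_with_logits, sigmoid
from dpetfusion.nn.layers import Adam, Module
from dpetfusion.nn.models import (
    INPUT_SHAPE,
    FeatureFusionNet,
    ModelConfig,
    ResNet3DSmall,
    build_model,
)


@dataclass
class TensorCase:
    """A standardized 64^3 tumor crop ready for the deep branch."""

    case_id: str
    grid: np.ndarray  # (64, 64, 64) float32, z-scored
    label: int


def tensorize(volume: Volume, mask: RoiMask, margin: int = 5, case_id: str = "", label: int = -1) -> TensorCase:
    """Crop with margin, resample to 64^3 and z-score within the crop.

    A constant crop z-scores to all zeros (guarded standard deviation).
    """
    cvol, cmask = crop_with_margin(volume, mask, margin)
    rvol, _ = resample_to_shape(cvol, cmask, INPUT_SHAPE)
    grid = rvol.data.astype(np.float32)
    sd = float(grid.std())
    grid = (grid - grid.mean()) / max(sd, 1e-6)
    return TensorCase(case_id=case_id, grid=grid.astype(np.float32), label=int(label))


def stack_cases(cases: list[TensorCase]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([c.grid for c in cases])[:, None].astype(np.float32)
    y = np.array([c.label for c in cases], dtype=np.float32)
    return X, y


def _prepool(X: np.ndarray, factor: int) -> np.ndarray:
    """Apply the CNN stem's average pooling once per dataset (pure speed)."""
    if factor <= 1 or X.shape[-1] != 64:  # already pre-pooled upstream
        return X
    n, c, d, h, w = X.shape
    return X.reshape(n, c, d // factor, factor, h // factor, factor, w // factor, factor).mean(
        axis=(3, 5, 7)
    )


def _model_inputs(model: Module, X: np.ndarray) -> np.ndarray:
    if isinstance(model, ResNet3DSmall):
        return _prepool(X, model.input_pool)
    if isinstance(model, FeatureFusionNet):
        return _prepool(X, model.backbone.input_pool)
    return X


def train_model(
    model: Module,
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    radiomics: np.ndarray | None = None,
) -> Module:
    """Minibatch Adam training with binary cross-entropy."""
    rng = np.random.default_rng(config.seed + 17)
    Xp = _model_inputs(model, X)
    params = model.parameters()
    scales = [1.0] * len(params)
    if isinstance(model, FeatureFusionNet):
        proj_ids = {id(p) for p in model.projection.parameters()}
        scales = [config.proj_lr_mult if id(p) in proj_ids else 1.0 for p in params]
    opt = Adam(params, lr=config.lr, weight_decay=config.weight_decay, lr_scales=scales)
    model.set_training(True)
    n = len(y)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:  # batch statistics need >= 2 cases
                continue
            xb = Tensor(Xp[idx])
            if radiomics is not None:
                logit = model(xb, Tensor(radiomics[idx]))
            else:
                logit = model(xb)
            loss = bce_with_logits(logit, y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
    model.set_training(False)
    return model


def predict_proba(
    model: Module,
    X: np.ndarray,
    radiomics: np.ndarray | None = None,
    batch_size: int = 32,
) -> np.ndarray:
    """Deterministic eval-mode probabilities in (0, 1)."""
    model.set_training(False)
    Xp = _model_inputs(model, X)
    out = []
    for start in range(0, len(Xp), batch_size):
        xb = Tensor(Xp[start : start + batch_size])
        if radiomics is not None:
            logit = model(xb, Tensor(radiomics[start : start + batch_size]))
        else:
            logit = model(xb)
        out.append(sigmoid(logit).data.ravel())
    return np.concatenate(out).astype(np.float64)


def _fold_indices(y: np.ndarray, folds: int, seed: int):
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def cv_select_and_train(
    cases: list[TensorCase],
    configs: list[ModelConfig],
    folds: int = 5,
    seed: int = 0,
    radiomics: np.ndarray | None = None,
    n_radiomics: int | None = None,
) -> tuple[ModelConfig, Module, np.ndarray, dict[str, float]]:
    """Select a configuration by mean OOF AUC, retrain it on all cases.

    Returns (chosen config, final model, out-of-fold probabilities of the
    chosen config, per-config mean OOF AUC report).
    """
    from dpetfusion.metrics import auc

    X, y = stack_cases(cases)
    for cls in (0, 1):
        if (y == cls).sum() < folds:
            raise ValueError(f"need at least {folds} cases of class {cls}")
    splits = _fold_indices(y, folds, seed)
    report: dict[str, float] = {}
    oofs: dict[str, np.ndarray] = {}
    for config in configs:
        config = replace(config, seed=seed if config.seed == 0 else config.seed)
        oof = np.zeros(len(y))
        for tr, va in splits:
            model = _build(config, radiomics, n_radiomics)
            train_model(
                model, X[tr], y[tr], config,
                radiomics=None if radiomics is None else radiomics[tr],
            )
            oof[va] = predict_proba(
                model, X[va], radiomics=None if radiomics is None else radiomics[va]
            )
        fold_aucs = [auc(oof[va], y[va]) for _, va in splits]
        report[config.name] = float(np.mean(fold_aucs))
        oofs[config.name] = oof
    best_name = max(report, key=report.get)
    best_config = next(c for c in configs if c.name == best_name)
    best_config = replace(best_config, seed=seed if best_config.seed == 0 else best_config.seed)
    final = _build(best_config, radiomics, n_radiomics)
    train_model(final, X, y, best_config, radiomics=radiomics)
    return best_config, final, oofs[best_name], report


def _build(config: ModelConfig, radiomics, n_radiomics) -> Module:
    if radiomics is not None or n_radiomics:
        return FeatureFusionNet(config, n_radiomics or radiomics.shape[1])
    return build_model(config)
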