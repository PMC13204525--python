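"""Branch fusion: decision-level stacking and feature-level residual injection.

Decision-level fusion trains a logistic meta-learner on the two branches'
logit-transformed probabilities. Training inputs are out-of-fold
probabilities (leakage-free); once tuned on the training cohort the
meta-learner is frozen and applied unchanged to test partitions.

Feature-level fusion projects the selected radiomics features into the
CNN's pooled representation (zero-initialized linear projection, residual
addition) and retrains the extended network end-to-end under the deep
branch's procedure; see :class:`dpetfusion.nn.models.FeatureFusionNet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROB_CLIP = 1e-6


@dataclass
class PredictionSet:
    """Per-case probabilities from one branch, with partition tags."""

    branch: str
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    # frame columns: case_id, partition, probability, out_of_fold (bool)

    @classmethod
    def build(cls, branch, case_ids, partitions, probabilities, out_of_fold=False) -> "PredictionSet":
        probs = np.asarray(probabilities, dtype=np.float64)
        if not np.all(np.isfinite(probs)):
            raise ValueError("probabilities must be finite")
        frame = pd.DataFrame(
            {
                "case_id": list(case_ids),
                "partition": list(partitions),
                "probability": probs,
                "out_of_fold": out_of_fold,
            }
        )
        if frame["case_id"].duplicated().any():
            raise ValueError("duplicate case ids in prediction set")
        return cls(branch=branch, frame=frame)

    def probabilities(self, partition: str | None = None) -> pd.Series:
        f = self.frame if partition is None else self.frame[self.frame.partition == partition]
        return f.set_index("case_id")["probability"]


def logit(p: np.ndarray) -> np.ndarray:
    """Logit with clipping to [1e-6, 1 - 1e-6] (exact 0/1 are clipped)."""
    p = np.clip(np.asarray(p, dtype=np.float64), PROB_CLIP, 1.0 - PROB_CLIP)
    return np.log(p / (1.0 - p))


@dataclass
class StackedMeta:
    """Frozen logistic meta-learner over logit-transformed branch outputs."""

    model: object
    branch_names: tuple[str, str]

    @property
    def weights(self) -> np.ndarray:
        return self.model.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    def predict(self, p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
        Z = np.column_stack([logit(p_a), logit(p_b)])
        return self.model.predict_proba(Z)[:, 1]


def stack_decision(
    p_a: np.ndarray,
    p_b: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    folds: int = 5,
    branch_names: tuple[str, str] = ("deep", "radiomics"),
) -> StackedMeta:
    """Fit the stacking meta-learner on training (out-of-fold) probabilities.

    The regularization strength is tuned by stratified-CV AUC on the
    training rows only.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import GridSearchCV, StratifiedKFold

    p_a, p_b = np.asarray(p_a), np.asarray(p_b)
    labels = np.asarray(labels).astype(int)
    if len(p_a) != len(labels) or len(p_b) != len(labels):
        raise ValueError("need both branch probabilities for every training case")
    Z = np.column_stack([logit(p_a), logit(p_b)])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        LogisticRegression(max_iter=2000),
        {"C": [0.01, 0.1, 1.0, 10.0, 100.0]},
        scoring="roc_auc",
        cv=skf,
        n_jobs=1,
    )
    gs.fit(Z, labels)
    return StackedMeta(model=gs.best_estimator_, branch_names=branch_names)


def feature_fusion_train(
    cases,
    radiomics_z: np.ndarray,
    labels: np.ndarray,
    config=None,
    seed: int = 0,
):
    """Train the feature-level fusion network end-to-end.

    ``radiomics_z`` must be the selected features z-scored with training
    statistics. Returns the fitted :class:`FeatureFusionNet`.
    """
    from dpetfusion.nn.models import FeatureFusionNet, ModelConfig
    from dpetfusion.nn.train import stack_cases, train_model

    if config is None:
        config = ModelConfig(seed=seed)
    X, y = stack_cases(cases)
    if radiomics_z.shape[0] != len(y):
        raise ValueError("radiomics rows must match cases")
    net = FeatureFusionNet(config, radiomics_z.shape[1])
    train_model(net, X, y, config, radiomics=radiomics_z.astype(np.float32))
    return net


def predict_fused_feature(net, cases, radiomics_z: np.ndarray) -> np.ndarray:
    from dpetfusion.nn.train import predict_proba, stack_cases

    X, _ = stack_cases(cases)
    return predict_proba(net, X, radiomics=radiomics_z.astype(np.float32))
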