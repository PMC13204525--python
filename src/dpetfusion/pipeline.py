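"""End-to-end experiment orchestration over a synthetic cohort.

Runs the full study protocol on a generated cohort: habitat segmentation,
per-region radiomics extraction, the selection cascade and classifiers,
the deep branch with CV-based model selection, the ITH branch, both fusion
modes, the clinical baseline, and per-partition evaluation. All fitting
happens on training rows; test partitions only ever pass through frozen
transforms and models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("dpetfusion")

from dpetfusion.habitats import segment_habitats
from dpetfusion.io import spawn_seeds
from dpetfusion.ith import fit_ith_model, ith_for_case
from dpetfusion.metrics import MetricReport, auc, baseline_clinical_model, threshold_metrics
from dpetfusion.nn.models import ModelConfig
from dpetfusion.nn.train import cv_select_and_train, predict_proba, stack_cases, tensorize
from dpetfusion.radiomics import (
    ExtractionProfile,
    SelectedFeatureSet,
    case_feature_vector,
    fit_radiomics_classifier,
    out_of_fold_probabilities,
    run_selection_cascade,
)
from dpetfusion.fusion import (
    StackedMeta,
    feature_fusion_train,
    predict_fused_feature,
    stack_decision,
)
from dpetfusion.synthetic import Cohort, materialize_case

PARTITION_ORDER = ("train", "test1", "test2")


@dataclass
class PipelineOptions:
    profile: ExtractionProfile = field(default_factory=ExtractionProfile)
    classifier_algos: tuple[str, ...] = ("LR",)
    deep_configs: list[ModelConfig] | None = None
    folds: int = 5
    sigma_mm: float = 1.0
    with_deep: bool = True
    with_ith: bool = True
    with_decision_fusion: bool = True
    with_feature_fusion: bool = True
    with_baseline: bool = True
    stacking_inputs: str = "oof"  # or "refit": optimistic, for comparison only
    seed: int = 0

    def resolved_deep_configs(self) -> list[ModelConfig]:
        if self.deep_configs is not None:
            return self.deep_configs
        return [ModelConfig(arch="resnet3d_small", name="resnet3d_small")]


@dataclass
class PipelineResult:
    options: PipelineOptions
    labels: dict[str, np.ndarray]
    case_ids: dict[str, list[str]]
    predictions: dict[str, dict[str, np.ndarray]]  # branch -> partition -> probs
    selection: SelectedFeatureSet | None = None
    classifier_reports: dict[str, float] = field(default_factory=dict)
    deep_report: dict[str, float] = field(default_factory=dict)
    deep_config: ModelConfig | None = None
    ith_pvalue: float | None = None
    models: dict[str, object] = field(default_factory=dict)
    feature_table: pd.DataFrame | None = None
    habitats_degenerate: int = 0

    def auc_of(self, branch: str, partition: str) -> float:
        return auc(self.predictions[branch][partition], self.labels[partition])

    def report(self, branch: str, partition: str, cutoff: float = 0.5) -> MetricReport:
        return threshold_metrics(self.predictions[branch][partition], self.labels[partition], cutoff)

    def branches(self) -> list[str]:
        return list(self.predictions)


def collect_case_data(
    cohort: Cohort,
    profile: ExtractionProfile,
    sigma_mm: float = 1.0,
    with_tensor: bool = True,
    with_ith: bool = False,
    prepool: int = 4,
    ith_seed: int = 0,
):
    """Materialize every case once; keep only compact per-case artifacts.

    Returns (feature rows, tensor grids, ith scores, degenerate-habitat
    count). Tensor grids are stored pre-pooled when ``prepool`` > 1 (a pure
    speed/memory device for the CNN path whose stem pools anyway).
    """
    feature_rows: dict[str, dict[str, float]] = {}
    tensors: dict[str, np.ndarray] = {}
    ith_scores: dict[str, float] = {}
    degenerate = 0
    for spec in cohort.specs:
        case = materialize_case(spec, cohort.config)
        hmap = segment_habitats(case.volume, case.mask, sigma_mm=sigma_mm)
        degenerate += int(hmap.degenerate_flag)
        vec, _missing = case_feature_vector(case.volume, case.mask, hmap, profile)
        feature_rows[spec.case_id] = vec
        if with_tensor:
            tc = tensorize(case.volume, case.mask, case_id=spec.case_id, label=spec.label)
            grid = tc.grid
            if prepool > 1:
                g = grid.shape[0] // prepool
                grid = grid.reshape(g, prepool, g, prepool, g, prepool).mean(axis=(1, 3, 5))
            tensors[spec.case_id] = grid.astype(np.float32)
        if with_ith:
            ith_scores[spec.case_id] = ith_for_case(case.volume, case.mask, seed=ith_seed).ith_score
    return feature_rows, tensors, ith_scores, degenerate


def build_partitioned_table(
    feature_rows: dict[str, dict[str, float]], cohort: Cohort
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, np.ndarray]]:
    """Assemble the cases x features table, imputing NaNs with *training* medians."""
    frame = pd.DataFrame.from_dict(feature_rows, orient="index")
    case_ids = {p: [s.case_id for s in cohort.specs_for(p)] for p in PARTITION_ORDER}
    train_medians = frame.loc[case_ids["train"]].median(axis=0)
    frame = frame.fillna(train_medians).fillna(0.0)
    labels = {
        p: np.array([s.label for s in cohort.specs_for(p)], dtype=int) for p in PARTITION_ORDER
    }
    return frame, case_ids, labels


def run_pipeline(cohort: Cohort, options: PipelineOptions | None = None) -> PipelineResult:
    options = options or PipelineOptions()
    seeds = spawn_seeds(options.seed, 8)
    configs = options.resolved_deep_configs()
    need_full_grid = any(c.arch != "resnet3d_small" for c in configs)
    prepool = 1 if need_full_grid else (configs[0].input_pool if configs else 4)

    feature_rows, tensors, ith_scores, degenerate = collect_case_data(
        cohort,
        options.profile,
        sigma_mm=options.sigma_mm,
        with_tensor=options.with_deep or options.with_feature_fusion,
        with_ith=options.with_ith,
        prepool=prepool,
        ith_seed=seeds[5],
    )
    table, case_ids, labels = build_partitioned_table(feature_rows, cohort)
    parts = [p for p in PARTITION_ORDER if len(case_ids[p])]
    logger.info(
        "collected %d cases (%d degenerate habitats), %d feature columns",
        len(table), degenerate, table.shape[1],
    )
    result = PipelineResult(
        options=options,
        labels=labels,
        case_ids=case_ids,
        predictions={},
        feature_table=table,
        habitats_degenerate=degenerate,
    )

    # ----- radiomics branch ------------------------------------------------
    X_train = table.loc[case_ids["train"]]
    y_train = labels["train"]
    selection = run_selection_cascade(
        X_train, y_train, folds=options.folds, seed=seeds[0]
    )
    result.selection = selection
    logger.info(
        "selection cascade: %d -> %d -> %d features (lambda %.4g)",
        len(selection.post_utest), len(selection.post_mrmr),
        len(selection.post_lasso), selection.lasso_lambda,
    )
    Z = {p: selection.transform(table.loc[case_ids[p]]) for p in parts}
    fitted = {}
    for algo in options.classifier_algos:
        clf = fit_radiomics_classifier(
            Z["train"], y_train, selection.post_lasso, algo=algo,
            folds=options.folds, seed=seeds[1],
        )
        fitted[algo] = clf
        result.classifier_reports[algo] = clf.cv_auc
        result.predictions[f"radiomics_{algo}"] = {
            p: clf.predict_proba(Z[p]) for p in parts
        }
    best_algo = max(fitted, key=lambda a: fitted[a].cv_auc)
    result.models["radiomics"] = fitted[best_algo]
    result.models["radiomics_algo"] = best_algo
    result.predictions["radiomics"] = result.predictions[f"radiomics_{best_algo}"]
    rad_oof = out_of_fold_probabilities(
        Z["train"], y_train, algo=best_algo, folds=options.folds, seed=seeds[1]
    )

    # ----- deep branch -----------------------------------------------------
    deep_oof = None
    if options.with_deep:
        from dpetfusion.nn.train import TensorCase

        train_cases = [
            TensorCase(cid, tensors[cid], int(lab))
            for cid, lab in zip(case_ids["train"], y_train)
        ]
        config, model, deep_oof, report = cv_select_and_train(
            train_cases, configs, folds=options.folds, seed=seeds[2]
        )
        result.deep_config = config
        result.deep_report = report
        result.models["deep"] = model
        result.predictions["deep"] = {}
        for p in parts:
            Xp = np.stack([tensors[cid] for cid in case_ids[p]])[:, None]
            result.predictions["deep"][p] = predict_proba(model, Xp)

    # ----- ITH branch ------------------------------------------------------
    if options.with_ith:
        scores = {p: np.array([ith_scores[cid] for cid in case_ids[p]]) for p in parts}
        try:
            ith_model, _, pval = fit_ith_model(scores["train"], y_train)
            result.ith_pvalue = pval
            result.models["ith"] = ith_model
            result.predictions["ith"] = {
                p: ith_model.predict_proba(scores[p].reshape(-1, 1))[:, 1] for p in parts
            }
        except ValueError:
            result.predictions["ith"] = {p: np.full(len(case_ids[p]), 0.5) for p in parts}

    # ----- decision fusion -------------------------------------------------
    if options.with_decision_fusion and deep_oof is not None:
        if options.stacking_inputs == "refit":
            meta_deep = result.predictions["deep"]["train"]
            meta_rad = result.predictions["radiomics"]["train"]
        else:
            meta_deep, meta_rad = deep_oof, rad_oof
        meta = stack_decision(meta_deep, meta_rad, y_train, seed=seeds[3])
        result.models["decision_fusion"] = meta
        result.predictions["decision_fusion"] = {
            p: meta.predict(
                result.predictions["deep"][p], result.predictions["radiomics"][p]
            )
            for p in parts
        }

    # ----- feature fusion --------------------------------------------------
    if options.with_feature_fusion:
        from dpetfusion.nn.train import TensorCase

        fusion_config = next(
            (c for c in configs if c.arch == "resnet3d_small"), ModelConfig()
        )
        train_cases = [
            TensorCase(cid, tensors[cid], int(lab))
            for cid, lab in zip(case_ids["train"], y_train)
        ]
        net = feature_fusion_train(
            train_cases, Z["train"], y_train, config=fusion_config, seed=seeds[4]
        )
        result.models["feature_fusion"] = net
        result.predictions["feature_fusion"] = {}
        for p in parts:
            pcases = [TensorCase(cid, tensors[cid], 0) for cid in case_ids[p]]
            result.predictions["feature_fusion"][p] = predict_fused_feature(net, pcases, Z[p])

    # ----- clinical baseline ----------------------------------------------
    if options.with_baseline:
        clin = cohort.clinical_frame().set_index("case_id")
        model = baseline_clinical_model(clin.loc[case_ids["train"]], y_train, seed=seeds[6])
        result.models["baseline"] = model
        result.predictions["baseline"] = {
            p: model.predict_proba(clin.loc[case_ids[p]])[:, 1] for p in parts
        }

    return result
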