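"""Synthetic dedicated-breast-PET-like cohorts with planted, controllable signal.

The real patient volumes are private, so every downstream branch is
developed and validated on synthetic cases that emulate the statistical
structure the analysis assumes:

* ellipsoidal tumors with a high-uptake core and lower-uptake rim, on a
  noisy soft-tissue background;
* SUV-like intensities — per-case SUVmax drawn around 32 within 14-65;
* two partially independent label-dependent signal channels: correlated
  texture whose spatial granularity differs by class (detectable by
  handcrafted features), and a variable number of high-uptake foci with a
  class-independent total intensity budget (a spatial-geometry signal aimed
  at convolutional models) — so fusion complementarity is testable;
* weakly informative clinical covariates (|log-odds| <= 0.4), mirroring a
  mediocre clinical baseline;
* a 129-case primary cohort split 70/30 (stratified) into train / test1,
  plus an independently generated, imbalanced 18-case test2 block.

Texture is Gaussian-filtered white noise with class-specific correlation
length; foci are Gaussian bumps at random in-mask positions. This is
deliberately schematic: it gives controllable habitat/heterogeneity
structure, not physically realistic PET reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from dpetfusion.io import (
    ClinicalRecord,
    CohortSplit,
    RoiMask,
    Volume,
    spawn_seeds,
    write_clinical_table,
    write_mask,
    write_volume,
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``*_by_label`` fields give (class-0, class-1) values; class 1 is pCR.
    ``clinical_effects`` are per-covariate log-odds shifts on standardized
    covariates (weak by default so the clinical baseline stays mediocre).
    """

    n_cases: int = 129
    prevalence: float = 0.655
    n_test2: int = 18
    prevalence_test2: float = 0.778
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    suv_mean: float = 32.2
    suv_sd: float = 9.0
    suv_range: tuple[float, float] = (14.0, 65.0)
    tumor_radius_range: tuple[float, float] = (5.0, 9.0)
    texture_granularity_by_label: tuple[float, float] = (5.0, 2.5)
    texture_amplitude: float = 0.28
    rim_core_contrast_by_label: tuple[float, float] = (0.5, 0.5)
    fragmentation_by_label: tuple[int, int] = (1, 3)
    focus_budget: float = 0.8
    focus_budget_split: bool = False  # split the budget across foci (True) or per-focus (False)
    focus_sigma_range: tuple[float, float] = (2.0, 3.0)
    background_level: float = 1.0
    background_noise: float = 0.25
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.10,
            "ki67": 0.30,
            "cT": -0.20,
            "cN": -0.15,
            "grade": 0.20,
            "regimen": 0.10,
            "suvmax": 0.25,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        lo, hi = self.suv_range
        if not (0 < lo <= self.suv_mean <= hi):
            raise ValueError("suv_range must be positive and contain suv_mean")
        if self.tumor_radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        max_extent_vox = 2 * self.tumor_radius_range[1] / min(self.spacing) + 4
        if max_extent_vox > min(self.grid_shape):
            raise ValueError(
                f"tumor radius up to {self.tumor_radius_range[1]} mm does not fit "
                f"the {self.grid_shape} grid at spacing {self.spacing}"
            )

    # -- named experimental conditions -------------------------------------

    def with_strong_texture(self) -> "GeneratorConfig":
        """Strong handcrafted-channel signal only (granularity 6 vs 2 mm)."""
        return replace(
            self,
            texture_granularity_by_label=(6.0, 2.0),
            texture_amplitude=0.35,
            fragmentation_by_label=(1, 1),
            rim_core_contrast_by_label=(0.5, 0.5),
        )

    def with_complementary_signal(self) -> "GeneratorConfig":
        """Texture signal for radiomics plus focal-geometry signal for CNNs."""
        return replace(
            self,
            texture_granularity_by_label=(5.0, 2.5),
            fragmentation_by_label=(1, 4),
            rim_core_contrast_by_label=(0.5, 0.5),
            focus_budget=0.8,
            focus_budget_split=False,
            focus_sigma_range=(2.0, 3.0),
        )

    def with_null_signal(self) -> "GeneratorConfig":
        """No class differences anywhere (negative control)."""
        return replace(
            self,
            texture_granularity_by_label=(3.5, 3.5),
            fragmentation_by_label=(1, 1),
            rim_core_contrast_by_label=(0.5, 0.5),
            clinical_effects={k: 0.0 for k in self.clinical_effects},
        )


@dataclass
class CaseSpec:
    """Deterministic recipe for one case: planted truth + clinical record.

    Volumes are rendered on demand (:func:`materialize_case`) so large
    cohorts never need to sit in memory at once.
    """

    case_id: str
    label: int
    seed: int
    truth: dict[str, float]
    clinical: ClinicalRecord


@dataclass
class SyntheticCase:
    case_id: str
    volume: Volume
    mask: RoiMask
    clinical: ClinicalRecord
    label: int
    truth: dict[str, float]


@dataclass
class Cohort:
    config: GeneratorConfig
    specs: list[CaseSpec]
    split: CohortSplit

    def specs_for(self, partition: str) -> list[CaseSpec]:
        wanted = set(self.split.cases(partition))
        return [s for s in self.specs if s.case_id in wanted]

    def clinical_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([vars(s.clinical) for s in self.specs])
        frame["partition"] = [self.split.assignment[s.case_id] for s in self.specs]
        return frame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.specs:
            rows.append({"case_id": s.case_id, "label": s.label, **s.truth})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-case generation
# ---------------------------------------------------------------------------


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _draw_params(config: GeneratorConfig, label: int, rng: np.random.Generator) -> dict[str, float]:
    eff = config.clinical_effects
    centered = label - 0.5
    r_lo, r_hi = config.tumor_radius_range
    semi_axes = rng.uniform(r_lo, r_hi, size=3)
    suv = _truncnorm(
        rng,
        config.suv_mean + eff.get("suvmax", 0.0) * centered * config.suv_sd,
        config.suv_sd,
        *config.suv_range,
    )
    params = {
        "granularity_mm": config.texture_granularity_by_label[label],
        "rim_core_contrast": config.rim_core_contrast_by_label[label],
        "n_foci": int(config.fragmentation_by_label[label]),
        "semi_a": float(semi_axes[0]),
        "semi_b": float(semi_axes[1]),
        "semi_c": float(semi_axes[2]),
        "suvmax": suv,
    }
    return params


def _draw_clinical(
    config: GeneratorConfig, case_id: str, label: int, suvmax: float, rng: np.random.Generator
) -> ClinicalRecord:
    eff = config.clinical_effects
    centered = label - 0.5
    age = _truncnorm(rng, 52.0 + 10.0 * eff.get("age", 0.0) * centered, 10.0, 25.0, 75.0)
    ki67 = _truncnorm(rng, 45.0 + 20.0 * eff.get("ki67", 0.0) * centered, 20.0, 1.0, 99.0)

    def _tilted_choice(values, base_logits, effect):
        logits = np.asarray(base_logits, dtype=float)
        ranks = np.arange(len(values)) - (len(values) - 1) / 2.0
        logits = logits + effect * centered * ranks
        p = np.exp(logits - logits.max())
        p /= p.sum()
        return values[rng.choice(len(values), p=p)]

    cT = _tilted_choice([1, 2, 3, 4], [np.log(0.03), np.log(0.60), np.log(0.12), np.log(0.25)],
                        eff.get("cT", 0.0))
    cN = _tilted_choice([0, 1, 2, 3], [np.log(0.10), np.log(0.58), np.log(0.15), np.log(0.17)],
                        eff.get("cN", 0.0))
    grade = _tilted_choice([2, 3], [np.log(0.37), np.log(0.63)], eff.get("grade", 0.0))
    regimen = _tilted_choice(["PCbHP", "TCbHP"], [np.log(0.32), np.log(0.68)],
                             eff.get("regimen", 0.0))
    return ClinicalRecord(
        case_id=case_id,
        age=round(age, 1),
        ki67=round(ki67, 1),
        cT=int(cT),
        cN=int(cN),
        grade=int(grade),
        regimen=str(regimen),
        suvmax=round(suvmax, 2),
        label=int(label),
    )


def make_case_spec(config: GeneratorConfig, case_id: str, label: int, seed: int) -> CaseSpec:
    rng = np.random.default_rng(seed)
    params = _draw_params(config, label, rng)
    clinical = _draw_clinical(config, case_id, label, params["suvmax"], rng)
    return CaseSpec(case_id=case_id, label=label, seed=seed, truth=params, clinical=clinical)


def materialize_case(spec: CaseSpec, config: GeneratorConfig) -> SyntheticCase:
    """Render the volume/mask for a case spec (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    _draw_params(config, spec.label, rng)  # replay the parameter stream
    _draw_clinical(config, spec.case_id, spec.label, spec.truth["suvmax"], rng)
    p = spec.truth
    shape = config.grid_shape
    spacing = np.asarray(config.spacing)

    # physical coordinates relative to a jittered tumor center
    center_vox = np.array(shape) / 2.0 + rng.uniform(-2, 2, size=3)
    grids = np.indices(shape).astype(np.float64)
    rel = [(grids[a] - center_vox[a]) * spacing[a] for a in range(3)]
    semi = np.array([p["semi_a"], p["semi_b"], p["semi_c"]])
    d = np.sqrt(sum((rel[a] / semi[a]) ** 2 for a in range(3)))  # 1.0 at the surface
    mask_arr = d <= 1.0

    # soft-tissue background: smoothed positive noise
    bg = config.background_level + config.background_noise * ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=1.5
    ) / 0.15  # rescale: smoothing shrinks the std by roughly this factor
    bg = np.clip(bg, 0.05, None)

    # core-rim radial profile (1 at center, contrast at the rim)
    contrast = p["rim_core_contrast"]
    profile = contrast + (1.0 - contrast) * np.exp(-((d / 0.55) ** 2))

    # correlated texture with class-specific granularity
    sig_vox = [p["granularity_mm"] / s for s in spacing]
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sig_vox)
    inmask_noise = noise[mask_arr]
    nstd = inmask_noise.std()
    if nstd > 0:
        noise = noise / nstd
    texture = config.texture_amplitude * noise

    # high-uptake foci: count differs by class, total budget does not
    n_foci = max(int(p["n_foci"]), 0)
    foci = np.zeros(shape)
    if n_foci > 0:
        candidates = np.argwhere(d <= 0.75)
        amp = config.focus_budget / n_foci if config.focus_budget_split else config.focus_budget
        for _ in range(n_foci):
            pos = candidates[rng.integers(len(candidates))]
            fsig = rng.uniform(*config.focus_sigma_range)  # mm
            fr2 = sum(((grids[a] - pos[a]) * spacing[a]) ** 2 for a in range(3))
            foci += amp * np.exp(-fr2 / (2 * fsig**2))

    tumor = profile * (1.0 + texture) + foci
    data = bg.copy()
    data[mask_arr] = np.clip(bg[mask_arr] + tumor[mask_arr], 0.05, None)
    # rescale in-mask uptake so the recorded SUVmax is exact
    cur = data[mask_arr].max()
    data[mask_arr] *= p["suvmax"] / cur

    volume = Volume(data, tuple(config.spacing))
    mask = RoiMask(mask_arr, tuple(config.spacing))
    return SyntheticCase(spec.case_id, volume, mask, spec.clinical, spec.label, dict(p))


def generate_case(config: GeneratorConfig, label: int, seed: int) -> SyntheticCase:
    spec = make_case_spec(config, f"case_{seed}", label, seed)
    return materialize_case(spec, config)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _draw_labels(rng: np.random.Generator, n: int, prevalence: float) -> np.ndarray:
    labels = (rng.random(n) < prevalence).astype(int)
    if labels.sum() < 2 or (n - labels.sum()) < 2:
        raise ValueError("prevalence so extreme that a label stratum is (nearly) empty")
    return labels


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Primary cohort split 70/30 (stratified) plus an independent test2 block."""
    if config.n_cases < 10:
        raise ValueError("need at least 10 primary cases")
    from sklearn.model_selection import train_test_split

    master = spawn_seeds(config.seed, 3)
    rng = np.random.default_rng(master[0])
    labels = _draw_labels(rng, config.n_cases, config.prevalence)
    case_seeds = spawn_seeds(master[1], config.n_cases + config.n_test2)

    specs = [
        make_case_spec(config, f"case_{i:04d}", int(labels[i]), case_seeds[i])
        for i in range(config.n_cases)
    ]
    idx_train, idx_test = train_test_split(
        np.arange(config.n_cases),
        test_size=0.3,
        stratify=labels,
        random_state=master[2] % (2**32 - 1),
    )
    assignment = {}
    for i in idx_train:
        assignment[specs[i].case_id] = "train"
    for i in idx_test:
        assignment[specs[i].case_id] = "test1"

    if config.n_test2 > 0:
        rng2 = np.random.default_rng(master[0] + 1)
        labels2 = (rng2.random(config.n_test2) < config.prevalence_test2).astype(int)
        for j in range(config.n_test2):
            spec = make_case_spec(
                config, f"case2_{j:04d}", int(labels2[j]), case_seeds[config.n_cases + j]
            )
            specs.append(spec)
            assignment[spec.case_id] = "test2"

    return Cohort(config=config, specs=specs, split=CohortSplit(assignment))


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write NIfTI volumes/masks, clinical CSV, split CSV and truth CSV."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    for spec in cohort.specs:
        case = materialize_case(spec, cohort.config)
        write_volume(case.volume, outdir / "images" / f"{spec.case_id}_pet.nii.gz")
        write_mask(case.mask, outdir / "images" / f"{spec.case_id}_mask.nii.gz")
    write_clinical_table([s.clinical for s in cohort.specs], outdir / "clinical.csv")
    cohort.split.to_frame().to_csv(outdir / "split.csv", index=False)
    cohort.truth_frame().to_csv(outdir / "truth.csv", index=False)
    return outdir
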