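"""Volumes, masks, clinical tables and the geometric preprocessing they share.

Conventions used throughout the package:

* voxel indices are 0-based and crops are reported as half-open ranges;
* intensities are interpolated trilinearly, masks with nearest neighbour
  (so masks stay binary);
* every randomized stage takes an explicit seed; :func:`spawn_seeds` fans a
  single pipeline seed out to per-stage seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


class GeometryError(ValueError):
    """Volume/mask geometry mismatch (shape or spacing)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D scalar grid of SUV-like intensities.

    Parameters
    ----------
    data:
        3D array of finite intensities (dimensionless, SUV-like scale).
    spacing:
        Per-axis physical voxel size in mm, all components positive.
    origin:
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise GeometryError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RoiMask:
    """A binary grid aligned to a :class:`Volume` (1 = tumor ROI)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise GeometryError(f"mask must be 3D, got shape {data.shape}")
        self.data = (data > 0).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def check_paired(self, volume: Volume) -> None:
        if self.data.shape != volume.data.shape:
            raise GeometryError(
                f"mask shape {self.data.shape} does not match volume shape {volume.data.shape}"
            )


REGIMENS = ("TCbHP", "PCbHP")


@dataclass
class ClinicalRecord:
    """Pre-treatment clinical covariates plus the binary pCR endpoint.

    ``label`` is 1 only for total pCR (breast and axilla); ``suvmax`` is the
    maximum standardized uptake value inside the tumor ROI.
    """

    case_id: str
    age: float
    ki67: float
    cT: int
    cN: int
    grade: int
    regimen: str
    suvmax: float
    label: int

    def __post_init__(self) -> None:
        if self.suvmax <= 0:
            raise ValueError("suvmax must be positive")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.regimen not in REGIMENS:
            raise ValueError(f"regimen must be one of {REGIMENS}, got {self.regimen!r}")


PARTITIONS = ("train", "test1", "test2")


@dataclass
class CohortSplit:
    """Disjoint partition tags (train / test1 / test2) per case id."""

    assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, part in self.assignment.items():
            if part not in PARTITIONS:
                raise ValueError(f"unknown partition {part!r} for case {cid}")

    def cases(self, partition: str) -> list[str]:
        return [cid for cid, p in self.assignment.items() if p == partition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": list(self.assignment), "partition": list(self.assignment.values())}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortSplit":
        return cls(dict(zip(frame["case_id"].astype(str), frame["partition"])))


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))
    return path


def write_mask(mask: RoiMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return Volume(data, spacing, origin)


def read_mask(path: str | Path) -> RoiMask:
    """Read a mask; any strictly positive value is treated as foreground."""
    vol = read_volume(path)
    return RoiMask(vol.data > 0, vol.spacing, vol.origin)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"case_id": str})
    return frame.set_index("case_id", drop=False)


def write_clinical_table(records: list[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame([vars(r) for r in records])
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# geometric preprocessing
# ---------------------------------------------------------------------------


def bounding_box(mask: RoiMask) -> tuple[tuple[int, int], ...]:
    """Tight half-open bounding box of the mask foreground."""
    if mask.n_foreground == 0:
        raise ValueError("mask is empty")
    out = []
    for axis in range(3):
        axes = tuple(a for a in range(3) if a != axis)
        prof = mask.data.any(axis=axes)
        idx = np.nonzero(prof)[0]
        out.append((int(idx[0]), int(idx[-1]) + 1))
    return tuple(out)


def crop_with_margin(
    volume: Volume, mask: RoiMask, margin: int = 5
) -> tuple[Volume, RoiMask]:
    """Crop to the mask bounding box dilated by ``margin`` voxels per axis.

    The margin is applied isotropically in index space and clipped to the
    image extent; the mask foreground count is unchanged.
    """
    mask.check_paired(volume)
    if margin < 0:
        raise ValueError("margin must be >= 0")
    box = bounding_box(mask)
    slices = tuple(
        slice(max(lo - margin, 0), min(hi + margin, volume.shape[axis]))
        for axis, (lo, hi) in enumerate(box)
    )
    new_origin = tuple(
        volume.origin[a] + slices[a].start * volume.spacing[a] for a in range(3)
    )
    cvol = Volume(volume.data[slices].copy(), volume.spacing, new_origin)
    cmask = RoiMask(mask.data[slices].copy(), mask.spacing, new_origin)
    return cvol, cmask


def resample_to_shape(
    volume: Volume, mask: RoiMask, target: tuple[int, int, int]
) -> tuple[Volume, RoiMask]:
    """Resample a volume/mask pair to ``target`` shape.

    Intensities are interpolated trilinearly, the mask with nearest
    neighbour so it stays binary. A constant volume stays exactly constant.
    """
    mask.check_paired(volume)
    target = tuple(int(t) for t in target)
    if any(t < 2 for t in target):
        raise ValueError(f"target components must be >= 2, got {target}")
    if any(s < 2 for s in volume.shape):
        raise ValueError(f"cannot resample a degenerate axis, shape {volume.shape}")
    factors = [t / s for t, s in zip(target, volume.shape)]
    vdata = ndimage.zoom(volume.data, factors, order=1, mode="nearest", grid_mode=True)
    mdata = ndimage.zoom(
        mask.data.astype(np.uint8), factors, order=0, mode="nearest", grid_mode=True
    )
    # zoom can be off by one voxel on awkward ratios; pad/trim defensively
    vdata = _fit_shape(vdata, target)
    mdata = _fit_shape(mdata, target)
    new_spacing = tuple(
        volume.spacing[a] * volume.shape[a] / target[a] for a in range(3)
    )
    return (
        Volume(vdata, new_spacing, volume.origin),
        RoiMask(mdata, new_spacing, volume.origin),
    )


def _fit_shape(arr: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    slices = tuple(slice(0, t) for t in target)
    arr = arr[slices]
    pad = [(0, t - s) for t, s in zip(target, arr.shape)]
    if any(p[1] for p in pad):
        arr = np.pad(arr, pad, mode="edge")
    return arr


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Fan a pipeline seed out to ``n`` independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]
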