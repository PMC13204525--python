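"""Metabolic habitat segmentation: high- vs low-uptake subregions.

Habitats are uptake-defined: 1-D k-means with k=2 on smoothed in-mask
intensities. In one dimension with exact convergence, 2-means reduces to an
optimal threshold, which is found exactly by scanning every candidate cut —
this removes all initialization sensitivity, so the segmentation is fully
deterministic (the ``seed`` argument is accepted for interface uniformity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dpetfusion.io import RoiMask, Volume

BACKGROUND, LOW_UPTAKE, HIGH_UPTAKE = 0, 1, 2


@dataclass
class HabitatMap:
    """Per-voxel habitat labels within the ROI.

    ``labels`` uses 0 = background, 1 = low-uptake, 2 = high-uptake.
    ``silhouette`` is the mean silhouette coefficient of the in-mask
    assignment (a quality diagnostic; k stays fixed at 2). When the ROI is
    degenerate (near-constant intensity or a habitat below ``min_size``),
    ``degenerate_flag`` is set and the whole ROI is labeled high-uptake.
    """

    labels: np.ndarray
    silhouette: float
    degenerate_flag: bool
    threshold: float | None = None

    def region_mask(self, which: str) -> np.ndarray:
        code = {"low": LOW_UPTAKE, "high": HIGH_UPTAKE}[which]
        return self.labels == code


def smooth(volume: Volume, sigma_mm: float = 1.0) -> Volume:
    """Gaussian smoothing with a physical-units kernel (sigma in mm).

    ``sigma=0`` is the identity. The kernel is normalized with reflective
    boundaries, so the grid mean is preserved up to float tolerance.
    """
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_mm == 0:
        return Volume(volume.data.copy(), volume.spacing, volume.origin)
    sig_vox = [sigma_mm / s for s in volume.spacing]
    out = ndimage.gaussian_filter(volume.data, sigma=sig_vox, mode="reflect")
    return Volume(out, volume.spacing, volume.origin)


def two_means_threshold(values: np.ndarray) -> tuple[float, float]:
    """Exact 1-D 2-means: returns (threshold, within-cluster SSE).

    Scans all cuts between consecutive sorted unique values; the optimal
    2-means partition in 1-D is always such a threshold cut.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise ValueError("need at least two distinct values")
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    k = np.arange(1, n)  # size of the low cluster
    sse_low = csq[k - 1] - csum[k - 1] ** 2 / k
    sum_high = csum[-1] - csum[k - 1]
    sq_high = csq[-1] - csq[k - 1]
    sse_high = sq_high - sum_high**2 / (n - k)
    sse = sse_low + sse_high
    # only cuts between distinct values are valid partitions
    valid = x[1:] > x[:-1]
    sse_valid = np.where(valid, sse, np.inf)
    best = int(np.argmin(sse_valid))
    threshold = 0.5 * (x[best] + x[best + 1])
    return float(threshold), float(sse_valid[best])


def silhouette_1d(values: np.ndarray, assign_high: np.ndarray) -> float:
    """Exact mean silhouette of a two-cluster 1-D partition (abs distance).

    Mean distances to own/other cluster are computed from prefix sums of the
    sorted values, O(n log n) — no pairwise matrix.
    """
    x = np.asarray(values, dtype=np.float64)
    labels = assign_high.astype(bool)
    n = x.size
    if labels.all() or (~labels).all():
        return 0.0
    sil = np.empty(n)
    for cl in (False, True):
        own = np.sort(x[labels == cl])
        other = np.sort(x[labels != cl])
        xs = x[labels == cl]
        a = _mean_abs_dist(xs, own, exclude_self=True)
        b = _mean_abs_dist(xs, other, exclude_self=False)
        denom = np.maximum(np.maximum(a, b), np.finfo(float).eps)
        s = np.where(own.size > 1, (b - a) / denom, 0.0)
        sil[labels == cl] = s
    return float(sil.mean())


def _mean_abs_dist(points: np.ndarray, sorted_ref: np.ndarray, exclude_self: bool) -> np.ndarray:
    csum = np.concatenate([[0.0], np.cumsum(sorted_ref)])
    m = sorted_ref.size
    pos = np.searchsorted(sorted_ref, points, side="right")
    left = pos * points - csum[pos]
    right = (csum[m] - csum[pos]) - (m - pos) * points
    total = left + right
    denom = m - 1 if exclude_self else m
    if denom <= 0:
        return np.zeros_like(points)
    return total / denom


def segment_habitats(
    volume: Volume,
    mask: RoiMask,
    sigma_mm: float = 1.0,
    min_size: int = 8,
    spread_tol: float = 1e-8,
    seed: int | None = None,
) -> HabitatMap:
    """Split the ROI into high- and low-uptake habitats.

    Intensities are smoothed, then partitioned by exact 1-D 2-means; the
    cluster with the higher centroid is labeled high-uptake. Degenerate
    ROIs (no intensity spread, or a habitat smaller than ``min_size``)
    get the whole ROI assigned to the high-uptake habitat with
    ``degenerate_flag`` set.
    """
    mask.check_paired(volume)
    if mask.n_foreground == 0:
        raise ValueError("empty ROI")
    smoothed = smooth(volume, sigma_mm)
    inmask = mask.data.astype(bool)
    values = smoothed.data[inmask]
    labels = np.zeros(volume.shape, dtype=np.int8)
    spread = float(values.max() - values.min())
    if values.size < 4 or spread <= spread_tol * max(abs(float(values.max())), 1.0):
        labels[inmask] = HIGH_UPTAKE
        return HabitatMap(labels, 0.0, True, None)
    threshold, _ = two_means_threshold(values)
    assign_high = values > threshold
    n_high, n_low = int(assign_high.sum()), int((~assign_high).sum())
    if min(n_high, n_low) < min_size:
        labels[inmask] = HIGH_UPTAKE
        return HabitatMap(labels, 0.0, True, threshold)
    labels[inmask] = np.where(assign_high, HIGH_UPTAKE, LOW_UPTAKE)
    sil = silhouette_1d(values, assign_high)
    return HabitatMap(labels, sil, False, threshold)
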