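"""2D intratumoral-heterogeneity (ITH) scoring on the largest tumor slice.

Per in-mask pixel, a 104-dimensional radiomic vector is computed on its
3x3 neighbourhood (19 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM +
14 GLDM + 5 NGTDM + 10 window-geometry shape features). Pixels are
k-means-clustered in z-scored feature space and mapped back to the slice;
the ITH score summarizes how fragmented the clusters are:

    ITH = 1 - sum_i p_i * (largest 4-connected component of cluster i)
                           / (total area of cluster i)

where p_i is cluster i's area fraction. The score is 0 exactly when every
cluster is one connected component and grows toward 1 with fragmentation.
This operationalizes "cluster area, connectivity and spatial distribution"
as a single scalar; higher = more heterogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from dpetfusion.io import RoiMask, Volume
from dpetfusion import texture as T


@dataclass
class PixelFeatureMap:
    """Per-pixel feature vectors for the in-mask pixels of one slice."""

    features: np.ndarray  # (n_pixels, 104)
    names: list[str]
    pixels: np.ndarray  # (n_pixels, 2) row/col indices
    slice_index: int
    shape: tuple[int, int]


@dataclass
class IthResult:
    label_map: np.ndarray  # 0 background, 1..k clusters
    k: int
    area_fractions: np.ndarray
    component_counts: np.ndarray
    largest_component_fractions: np.ndarray
    ith_score: float
    silhouette: float


def select_max_slice(volume: Volume, mask: RoiMask) -> tuple[np.ndarray, np.ndarray, int]:
    """Axial slice with the largest in-mask area; ties -> lowest index."""
    mask.check_paired(volume)
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    areas = mask.data.sum(axis=(1, 2))
    idx = int(np.argmax(areas))  # argmax returns the first maximum
    return volume.data[idx], mask.data[idx].astype(bool), idx


@lru_cache(maxsize=512)
def _window_shape_features(pattern: int) -> tuple[float, ...]:
    """Shape of a 3x3 in-mask window geometry, memoized by its 9-bit pattern."""
    bits = np.array([(pattern >> i) & 1 for i in range(9)], dtype=bool).reshape(3, 3)
    vals = T.shape2d_features(bits)
    return tuple(vals[k] for k in _SHAPE2D_KEYS)


_SHAPE2D_KEYS = [
    "PixelSurface",
    "Perimeter",
    "PerimeterSurfaceRatio",
    "Sphericity",
    "MaximumDiameter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Elongation",
    "Extent",
    "Solidity",
]


def pixel_feature_names() -> list[str]:
    names = [f"firstorder|{k}" for k in T.firstorder_features(np.array([1.0, 2.0]), with_std=True)]
    disc = np.array([[1, 2], [2, 1]], dtype=np.int32)
    names += [f"glcm|{k}" for k in T.glcm_features(T.glcm_matrix(disc, 2))]
    names += [f"glrlm|{k}" for k in T.glrlm_features(T.glrlm_matrix(disc, 2), 4)]
    names += [f"glszm|{k}" for k in T.glszm_features(T.glszm_matrix(disc, 2), 4)]
    names += [f"gldm|{k}" for k in T.gldm_features(T.gldm_matrix(disc, 2))]
    names += [f"ngtdm|{k}" for k in T.ngtdm_features(*T.ngtdm_stats(disc, 2))]
    names += [f"shape2d|{k}" for k in _SHAPE2D_KEYS]
    return names


def pixel_features(image: np.ndarray, mask: np.ndarray, n_bins: int = 8) -> PixelFeatureMap:
    """104 features per in-mask pixel from its 3x3 (mask-intersected) window.

    Border pixels use the in-mask part of their window; window
    discretization uses a fixed bin count within the window. Computation is
    batched across windows (:mod:`dpetfusion.pixelbank`); the per-window
    path :func:`pixel_features_reference` is the equivalence oracle.
    """
    from dpetfusion.pixelbank import pixel_feature_matrix

    mask = mask.astype(bool)
    if mask.sum() < 9:
        raise ValueError("mask must cover at least 9 pixels")
    pixels, feats = pixel_feature_matrix(image, mask, n_bins)
    return PixelFeatureMap(feats, pixel_feature_names(), pixels, -1, mask.shape)


def pixel_features_reference(image: np.ndarray, mask: np.ndarray, n_bins: int = 8) -> PixelFeatureMap:
    """Window-by-window reference implementation of :func:`pixel_features`."""
    mask = mask.astype(bool)
    if mask.sum() < 9:
        raise ValueError("mask must cover at least 9 pixels")
    names = pixel_feature_names()
    pixels = np.argwhere(mask)
    rows_out = np.empty((len(pixels), len(names)), dtype=np.float64)
    nrow, ncol = mask.shape
    for p, (r, c) in enumerate(pixels):
        r0, r1 = max(r - 1, 0), min(r + 2, nrow)
        c0, c1 = max(c - 1, 0), min(c + 2, ncol)
        win = image[r0:r1, c0:c1]
        wmask = mask[r0:r1, c0:c1]
        vals = win[wmask]
        disc, n_levels = T.discretize(win, wmask, n_bins)
        feats: list[float] = []
        feats.extend(T.firstorder_features(vals, 1.0, n_bins, with_std=True).values())
        n_pix = int(wmask.sum())
        feats.extend(T.glcm_features(T.glcm_matrix(disc, n_levels)).values())
        feats.extend(T.glrlm_features(T.glrlm_matrix(disc, n_levels), n_pix).values())
        feats.extend(T.glszm_features(T.glszm_matrix(disc, n_levels), n_pix).values())
        feats.extend(T.gldm_features(T.gldm_matrix(disc, n_levels)).values())
        feats.extend(T.ngtdm_features(*T.ngtdm_stats(disc, n_levels)).values())
        # geometry of the in-mask window, embedded in a fixed 3x3 frame
        frame = np.zeros((3, 3), dtype=bool)
        frame[r0 - (r - 1) : r1 - (r - 1), c0 - (c - 1) : c1 - (c - 1)] = wmask
        pattern = int((frame.ravel() * (1 << np.arange(9))).sum())
        feats.extend(_window_shape_features(pattern))
        rows_out[p] = feats
    return PixelFeatureMap(rows_out, names, pixels, -1, mask.shape)


def cluster_pixels(
    fmap: PixelFeatureMap, k: int | None = None, seed: int = 0, k_range=(2, 5)
) -> tuple[np.ndarray, int, float]:
    """K-means on z-scored pixel vectors; k by silhouette unless fixed.

    Returns (label map with clusters 1..k and background 0, k, silhouette).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    X = fmap.features
    n = X.shape[0]
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    if k is not None:
        if n < k:
            raise ValueError(f"only {n} pixels for k={k}")
        km = KMeans(n_clusters=k, n_init=4, random_state=seed).fit(Z)
        labels, sil = km.labels_, _safe_silhouette(Z, km.labels_)
        best_k = k
    else:
        best = None
        for kk in range(k_range[0], k_range[1] + 1):
            if n < kk:
                break
            km = KMeans(n_clusters=kk, n_init=4, random_state=seed).fit(Z)
            sil = _safe_silhouette(Z, km.labels_)
            if best is None or sil > best[0]:
                best = (sil, kk, km.labels_)
        sil, best_k, labels = best
    label_map = np.zeros(fmap.shape, dtype=np.int32)
    label_map[fmap.pixels[:, 0], fmap.pixels[:, 1]] = labels + 1
    return label_map, best_k, float(sil)


def _safe_silhouette(Z: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    if len(np.unique(labels)) < 2:
        return -1.0
    try:
        return float(silhouette_score(Z, labels))
    except ValueError:
        return -1.0


FOUR_CONNECTIVITY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def ith_score(label_map: np.ndarray) -> IthResult:
    """Area-weighted largest-component complement of the cluster map."""
    label_map = np.asarray(label_map)
    clusters = np.unique(label_map[label_map > 0])
    if clusters.size == 0:
        raise ValueError("empty label map")
    total = float((label_map > 0).sum())
    fracs, comp_counts, largest_fracs = [], [], []
    score = 0.0
    for cl in clusters:
        binary = label_map == cl
        area = float(binary.sum())
        lab, n_comp = ndimage.label(binary, structure=FOUR_CONNECTIVITY)
        sizes = np.bincount(lab.ravel())[1:]
        largest = float(sizes.max())
        p = area / total
        fracs.append(p)
        comp_counts.append(int(n_comp))
        largest_fracs.append(largest / area)
        score += p * (largest / area)
    return IthResult(
        label_map=label_map,
        k=int(clusters.size),
        area_fractions=np.array(fracs),
        component_counts=np.array(comp_counts),
        largest_component_fractions=np.array(largest_fracs),
        ith_score=float(1.0 - score),
        silhouette=np.nan,
    )


def ith_for_case(
    volume: Volume, mask: RoiMask, k: int | None = None, seed: int = 0, n_bins: int = 8
) -> IthResult:
    """Full per-case chain: max slice -> pixel features -> clusters -> score."""
    image2d, mask2d, idx = select_max_slice(volume, mask)
    fmap = pixel_features(image2d, mask2d, n_bins=n_bins)
    fmap.slice_index = idx
    label_map, best_k, sil = cluster_pixels(fmap, k=k, seed=seed)
    result = ith_score(label_map)
    result.silhouette = sil
    return result


def fit_ith_model(scores: np.ndarray, labels: np.ndarray):
    """Univariate logistic model on the ITH score, with AUC and rank-test p."""
    from scipy import stats as sps
    from sklearn.linear_model import LogisticRegression

    from dpetfusion.metrics import auc

    scores = np.asarray(scores, dtype=np.float64).reshape(-1, 1)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes")
    if np.ptp(scores) == 0:
        raise ValueError("constant scores cannot be modeled")
    model = LogisticRegression(max_iter=1000).fit(scores, labels)
    a = auc(scores.ravel(), labels)
    u = sps.mannwhitneyu(
        scores[labels == 1].ravel(), scores[labels == 0].ravel(), alternative="two-sided"
    )
    return model, float(a), float(u.pvalue)
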