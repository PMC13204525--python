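"""Gray-level texture matrices and handcrafted feature definitions.

Implements the standard radiomics feature families (first-order, GLCM,
GLRLM, GLSZM, GLDM, NGTDM, 3D and 2D shape) following IBSI-style
definitions. Everything is dimension-agnostic where the mathematics is
(matrices are built from N-d discretized grids), so the same code backs the
3D region bank and the 2D per-pixel heterogeneity features.

Conventions pinned here:

* discretization uses a fixed bin count inside the region (gray levels
  ``1..n_bins``; 0 marks out-of-region voxels);
* co-occurrence/run matrices are accumulated over all unique directions
  (13 in 3D, 4 in 2D) and features are computed on the aggregate matrix;
* GLCM matrices are symmetrized; runs/zones/dependences use full
  (26-/8-) connectivity for zones and dependences.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

EPS = np.finfo(np.float64).eps


# ---------------------------------------------------------------------------
# discretization and offsets
# ---------------------------------------------------------------------------


def discretize(image: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> tuple[np.ndarray, int]:
    """Fixed-bin-count discretization inside ``mask``.

    Returns an integer grid with levels ``1..n_levels`` inside the mask and
    0 outside. A constant region collapses to a single level.
    """
    mask = mask.astype(bool)
    vals = image[mask]
    if vals.size == 0:
        raise ValueError("empty region")
    lo, hi = float(vals.min()), float(vals.max())
    disc = np.zeros(image.shape, dtype=np.int32)
    if hi - lo <= 0:
        disc[mask] = 1
        return disc, n_bins
    # right-open bins except the last; level = 1..n_bins
    scaled = np.floor((image[mask] - lo) / (hi - lo) * n_bins).astype(np.int32) + 1
    disc[mask] = np.clip(scaled, 1, n_bins)
    return disc, n_bins


def unique_directions(ndim: int) -> list[tuple[int, ...]]:
    """Unique (up to sign) unit-step directions: 13 in 3D, 4 in 2D."""
    out = []
    for off in product((-1, 0, 1), repeat=ndim):
        if any(off) and off > tuple(-o for o in off):
            out.append(off)
    return out


def neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    """All nonzero offsets in {-1,0,1}^ndim (26 in 3D, 8 in 2D)."""
    return [off for off in product((-1, 0, 1), repeat=ndim) if any(off)]


def _shifted(arr: np.ndarray, off: tuple[int, ...], fill) -> np.ndarray:
    """Array of values at position p + off, padded with ``fill``."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for o, n in zip(off, arr.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def glcm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix aggregated over all directions."""
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    for off in unique_directions(disc.ndim):
        nb = _shifted(disc, off, 0)
        valid = (disc > 0) & (nb > 0)
        a = disc[valid] - 1
        b = nb[valid] - 1
        if a.size:
            counts += np.bincount(
                a * n_levels + b, minlength=n_levels * n_levels
            ).reshape(n_levels, n_levels)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def glrlm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length matrix P[i, j-1] = #runs of level i+1 with length j.

    Runs are maximal same-level segments along each of the unique
    directions; the matrix aggregates all directions. Run starts and ends
    are matched by sorting on a scalar (line id, step) key.
    """
    valid = disc > 0
    max_len = 1
    coords = np.indices(disc.shape, dtype=np.int64)
    S = max(disc.shape)
    B = 2 * S + 1
    per_dir = []
    for off in unique_directions(disc.ndim):
        prev = _shifted(disc, tuple(-o for o in off), -1)
        nxt = _shifted(disc, off, -1)
        starts = valid & (prev != disc)
        ends = valid & (nxt != disc)
        # integer step index along the direction and a scalar per-line key
        axis = next(i for i, o in enumerate(off) if o != 0)
        t = coords[axis] if off[axis] > 0 else -coords[axis]
        key = t.copy()
        mult = S + 1
        for a in range(disc.ndim):
            key += ((coords[a] - t * off[a]) + S) * mult
            mult *= B
        k_s = key[starts]
        order_s = np.argsort(k_s, kind="stable")
        t_s = t[starts][order_s]
        g_s = disc[starts][order_s]
        k_e = key[ends]
        t_e = t[ends][np.argsort(k_e, kind="stable")]
        lengths = t_e - t_s + 1
        per_dir.append((g_s, lengths))
        if lengths.size:
            max_len = max(max_len, int(lengths.max()))
    mat = np.zeros((n_levels, max_len), dtype=np.float64)
    for g, ln in per_dir:
        if g.size:
            np.add.at(mat, (g - 1, ln - 1), 1.0)
    return mat


def glszm_matrix(disc: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix S[i, j-1] = #connected zones of level i+1, size j."""
    structure = np.ones((3,) * disc.ndim, dtype=int)
    zones = []
    max_size = 1
    for g in range(1, n_levels + 1):
        binary = disc == g
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones.append((g, sizes))
        max_size = max(max_size, int(sizes.max()))
    mat = np.zeros((n_levels, max_size), dtype=np.float64)
    for g, sizes in zones:
        np.add.at(mat, (g - 1, sizes - 1), 1.0)
    return mat


def gldm_matrix(disc: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix D[i, j] = #voxels of level i+1 with j dependent neighbours."""
    valid = disc > 0
    dep = np.zeros(disc.shape, dtype=np.int32)
    for off in neighbor_offsets(disc.ndim):
        nb = _shifted(disc, off, 0)
        dep += ((np.abs(nb - disc) <= alpha) & (nb > 0)).astype(np.int32)
    g = disc[valid] - 1
    d = dep[valid]
    max_dep = int(d.max()) if d.size else 0
    mat = np.zeros((n_levels, max_dep + 1), dtype=np.float64)
    np.add.at(mat, (g, d), 1.0)
    return mat


def ngtdm_stats(disc: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbourhood gray-tone difference statistics.

    Returns ``(n_i, p_i, s_i)`` per gray level: voxel counts, probabilities
    and the summed absolute differences from the mean of the valid
    neighbourhood.
    """
    valid = disc > 0
    nb_sum = np.zeros(disc.shape, dtype=np.float64)
    nb_cnt = np.zeros(disc.shape, dtype=np.float64)
    for off in neighbor_offsets(disc.ndim):
        nb = _shifted(disc, off, 0)
        nb_sum += np.where(nb > 0, nb, 0.0)
        nb_cnt += (nb > 0).astype(np.float64)
    has_nb = valid & (nb_cnt > 0)
    diff = np.zeros(disc.shape, dtype=np.float64)
    diff[has_nb] = np.abs(disc[has_nb] - nb_sum[has_nb] / nb_cnt[has_nb])
    n_i = np.bincount((disc[has_nb] - 1), minlength=n_levels).astype(np.float64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    np.add.at(s_i, disc[has_nb] - 1, diff[has_nb])
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# feature computations
# ---------------------------------------------------------------------------


def firstorder_features(
    values: np.ndarray, voxel_volume: float = 1.0, n_bins: int = 32, with_std: bool = False
) -> dict[str, float]:
    """First-order statistics of in-region intensities (18; 19 with std)."""
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())
    std = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        hist = np.bincount(
            np.clip(np.floor((x - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1),
            minlength=n_bins,
        )
    else:
        hist = np.array([n])
    p = hist[hist > 0] / n
    # relative guard: float rounding gives constant arrays a tiny nonzero std
    if std > 1e-10 * max(abs(mean), 1.0):
        z = (x - mean) / std
        skew = float((z**3).mean())
        kurt = float((z**4).mean())  # Pearson convention: 3.0 for a Gaussian
    else:
        skew, kurt = 0.0, 0.0
    out = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(voxel_volume * (x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": lo,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": hi,
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": hi - lo,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }
    if with_std:
        out["StandardDeviation"] = std
    return out


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """24 co-occurrence features from a normalized symmetric GLCM."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma = float(np.sqrt(((i - mu) ** 2 * px).sum()))
    # diagonal (difference) and cross (sum) marginals
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in range(ng)])
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in range(2, 2 * ng + 1)])
    nz = P > 0
    joint_ent = float(-(P[nz] * np.log2(P[nz])).sum())
    pdnz = p_diff > 0
    psnz = p_sum > 0
    diff_avg = float((k_diff * p_diff).sum())
    autoc = float((ii * jj * P).sum())
    # information measures
    pxpy = np.outer(px, px)
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    both = nz & (pxpy > 0)
    hxy1 = float(-(P[both] * np.log2(pxpy[both])).sum())
    hxy2 = float(-(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])).sum())
    imc1 = (joint_ent - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_ent))
    imc2 = float(np.sqrt(max(arg, 0.0)))
    # maximal correlation coefficient
    with np.errstate(divide="ignore", invalid="ignore"):
        Q = np.einsum("ik,jk->ij", P, P / np.maximum(px[None, :], EPS)) / np.maximum(
            px[:, None], EPS
        )
    Q[~np.isfinite(Q)] = 0.0
    if int((px > 0).sum()) < 2:  # single occupied level: degenerate, perfectly dependent
        mcc = 1.0
    else:
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(eig[-2], 0.0)))
    if sigma > 0:
        corr = (autoc - mu * mu) / (sigma * sigma)
    else:
        corr = 1.0
    inv_var_mask = np.abs(ii - jj) > 0
    return {
        "Autocorrelation": autoc,
        "JointAverage": mu,
        "ClusterProminence": float((((ii + jj) - 2 * mu) ** 4 * P).sum()),
        "ClusterShade": float((((ii + jj) - 2 * mu) ** 3 * P).sum()),
        "ClusterTendency": float((((ii + jj) - 2 * mu) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff[pdnz] * np.log2(p_diff[pdnz])).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((P[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": joint_ent,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum[psnz] * np.log2(p_sum[psnz])).sum()),
        "SumSquares": float(((ii - mu) ** 2 * P).sum()),
    }


def _run_zone_features(mat: np.ndarray, n_voxels: int, prefix: tuple[str, str, str]) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature set (16 features each).

    ``prefix`` provides the family-specific name fragments, e.g.
    ``("Run", "ShortRun", "LongRun")`` or ``("Zone", "SmallArea", "LargeArea")``.
    """
    axis_name, small, large = prefix
    nr = mat.sum()
    if nr == 0:
        return {}
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    pg = mat.sum(axis=1)  # per gray level
    pj = mat.sum(axis=0)  # per run length / zone size
    p = mat / nr
    mu_i = float((i * p.sum(axis=1)).sum())
    mu_j = float((j * p.sum(axis=0)).sum())
    nzp = p[p > 0]
    gl = "GrayLevel"
    if axis_name == "Zone":
        var_names = ("GrayLevelVariance", "ZoneVariance", "ZoneEntropy")
        nonuni = ("GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
                  "SizeZoneNonUniformity", "SizeZoneNonUniformityNormalized", "ZonePercentage")
    else:
        var_names = ("GrayLevelVariance", "RunVariance", "RunEntropy")
        nonuni = ("GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
                  "RunLengthNonUniformity", "RunLengthNonUniformityNormalized", "RunPercentage")
    return {
        f"{small}Emphasis": float((mat / j[None, :] ** 2).sum() / nr),
        f"{large}Emphasis": float((mat * j[None, :] ** 2).sum() / nr),
        nonuni[0]: float((pg**2).sum() / nr),
        nonuni[1]: float((pg**2).sum() / nr**2),
        nonuni[2]: float((pj**2).sum() / nr),
        nonuni[3]: float((pj**2).sum() / nr**2),
        nonuni[4]: float(nr / n_voxels),
        var_names[0]: float((p * (i[:, None] - mu_i) ** 2).sum()),
        var_names[1]: float((p * (j[None, :] - mu_j) ** 2).sum()),
        var_names[2]: float(-(nzp * np.log2(nzp)).sum()),
        f"Low{gl}{axis_name}Emphasis" if axis_name == "Run" else f"Low{gl}ZoneEmphasis": float(
            (mat / i[:, None] ** 2).sum() / nr
        ),
        f"High{gl}{axis_name}Emphasis" if axis_name == "Run" else f"High{gl}ZoneEmphasis": float(
            (mat * i[:, None] ** 2).sum() / nr
        ),
        f"{small}Low{gl}Emphasis": float((mat / (i[:, None] ** 2 * j[None, :] ** 2)).sum() / nr),
        f"{small}High{gl}Emphasis": float((mat * i[:, None] ** 2 / j[None, :] ** 2).sum() / nr),
        f"{large}Low{gl}Emphasis": float((mat * j[None, :] ** 2 / i[:, None] ** 2).sum() / nr),
        f"{large}High{gl}Emphasis": float((mat * i[:, None] ** 2 * j[None, :] ** 2).sum() / nr),
    }


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(mat, n_voxels, ("Run", "ShortRun", "LongRun"))


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(mat, n_voxels, ("Zone", "SmallArea", "LargeArea"))


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    """14 gray-level dependence features; dependence size j = count + 1."""
    nz_total = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)  # dependence count + 1
    p = mat / nz_total
    pg = mat.sum(axis=1)
    pd = mat.sum(axis=0)
    mu_i = float((i * p.sum(axis=1)).sum())
    mu_j = float((j * p.sum(axis=0)).sum())
    nzp = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((mat / j[None, :] ** 2).sum() / nz_total),
        "LargeDependenceEmphasis": float((mat * j[None, :] ** 2).sum() / nz_total),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz_total),
        "DependenceNonUniformity": float((pd**2).sum() / nz_total),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz_total**2),
        "GrayLevelVariance": float((p * (i[:, None] - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j[None, :] - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(nzp * np.log2(nzp)).sum()),
        "LowGrayLevelEmphasis": float((mat / i[:, None] ** 2).sum() / nz_total),
        "HighGrayLevelEmphasis": float((mat * i[:, None] ** 2).sum() / nz_total),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (mat / (i[:, None] ** 2 * j[None, :] ** 2)).sum() / nz_total
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (mat * i[:, None] ** 2 / j[None, :] ** 2).sum() / nz_total
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (mat * j[None, :] ** 2 / i[:, None] ** 2).sum() / nz_total
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (mat * i[:, None] ** 2 * j[None, :] ** 2).sum() / nz_total
        ),
    }


def ngtdm_features(n_i: np.ndarray, p_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    """Coarseness, Contrast, Busyness, Complexity, Strength."""
    present = p_i > 0
    ngp = int(present.sum())
    n = n_i.sum()
    i = np.arange(1, p_i.size + 1, dtype=np.float64)
    coars_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6  # pinned degenerate cap
    if ngp > 1 and n > 0:
        pij = np.outer(p_i, p_i)
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(((pij * dij2).sum() / (ngp * (ngp - 1))) * (s_i.sum() / n))
        busy_den = float(
            np.abs(i[present, None] * p_i[present, None] - i[None, present] * p_i[None, present]).sum()
        )
        busyness = float((p_i * s_i).sum() / busy_den) if busy_den > 0 else 0.0
        ip = np.ix_(present, present)
        pi_p = p_i[present]
        i_p = i[present]
        s_p = s_i[present]
        num = np.abs(i_p[:, None] - i_p[None, :]) * (
            pi_p[:, None] * s_p[:, None] + pi_p[None, :] * s_p[None, :]
        ) / (pi_p[:, None] + pi_p[None, :])
        complexity = float(num.sum() / n)
        strength_num = float(
            ((pi_p[:, None] + pi_p[None, :]) * (i_p[:, None] - i_p[None, :]) ** 2).sum()
        )
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


def _pca_axis_lengths(coords_mm: np.ndarray) -> np.ndarray:
    """Descending 4*sqrt(eigenvalue) axis lengths of the coordinate cloud."""
    centered = coords_mm - coords_mm.mean(axis=0)
    cov = centered.T @ centered / coords_mm.shape[0]
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    return 4.0 * np.sqrt(np.maximum(eig, 0.0))


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) == 0:
        return 0.0
    if len(points) == 1:
        return 0.0
    if len(points) > 4:
        try:
            from scipy.spatial import ConvexHull

            points = points[ConvexHull(points, qhull_options="QJ").vertices]
        except Exception:
            pass
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def shape3d_features(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    """14 three-dimensional shape descriptors of a binary region.

    Surface quantities come from a marching-cubes mesh of the mask; axis
    lengths from PCA of the voxel coordinate cloud (pyradiomics-style
    4*sqrt(eigenvalue) convention).
    """
    from skimage import measure

    mask = mask.astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region")
    voxel_vol = float(np.prod(spacing))
    coords = np.argwhere(mask).astype(np.float64) * np.asarray(spacing)
    padded = np.pad(mask.astype(np.float64), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
        cross = np.cross(b - a, c - a)
        surface = float(0.5 * np.linalg.norm(cross, axis=1).sum())
        mesh_vol = float(abs((a * np.cross(b, c)).sum() / 6.0))
    except (RuntimeError, ValueError):  # e.g. single-voxel masks
        surface = float(2 * (spacing[0] * spacing[1] + spacing[0] * spacing[2] + spacing[1] * spacing[2]))
        mesh_vol = voxel_vol * n
    axes = _pca_axis_lengths(coords)
    major, minor, least = axes
    sphericity = float((36 * np.pi * mesh_vol**2) ** (1.0 / 3.0) / surface) if surface > 0 else 0.0
    diam3d = _max_pairwise(coords)
    # in-plane maximum diameters for the three orthogonal plane families
    vox = np.argwhere(mask)
    diam_planes = []
    for axis in range(3):
        best = 0.0
        other = [a for a in range(3) if a != axis]
        for idx in np.unique(vox[:, axis]):
            sel = coords[vox[:, axis] == idx][:, other]
            best = max(best, _max_pairwise(sel))
        diam_planes.append(best)
    return {
        "VoxelVolume": voxel_vol * n,
        "MeshVolume": mesh_vol,
        "SurfaceArea": surface,
        "SurfaceVolumeRatio": surface / mesh_vol if mesh_vol > 0 else 0.0,
        "Sphericity": sphericity,
        "Maximum3DDiameter": diam3d,
        "Maximum2DDiameterSlice": diam_planes[0],
        "Maximum2DDiameterColumn": diam_planes[1],
        "Maximum2DDiameterRow": diam_planes[2],
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(minor / major)) if major > 0 else 1.0,
        "Flatness": float(np.sqrt(least / major)) if major > 0 else 1.0,
    }


def shape2d_features(mask2d: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> dict[str, float]:
    """10 two-dimensional shape descriptors of a binary blob."""
    from skimage import measure

    mask2d = mask2d.astype(bool)
    n = int(mask2d.sum())
    if n == 0:
        raise ValueError("empty 2D region")
    pix_area = float(spacing[0] * spacing[1])
    area = n * pix_area
    lab = mask2d.astype(np.uint8)
    props = measure.regionprops(lab)[0]
    perimeter = float(props.perimeter) * float(np.sqrt(pix_area))
    if perimeter <= 0:  # single pixel
        perimeter = float(2 * (spacing[0] + spacing[1]))
    coords = np.argwhere(mask2d).astype(np.float64) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    major, minor = 4.0 * np.sqrt(np.maximum(eig, 0.0))
    return {
        "PixelSurface": area,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / area,
        "Sphericity": float(2.0 * np.sqrt(np.pi * area) / perimeter),
        "MaximumDiameter": _max_pairwise(coords),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": float(np.sqrt(minor / major)) if major > 0 else 1.0,
        "Extent": float(props.extent),
        "Solidity": float(props.solidity),
    }


# ---------------------------------------------------------------------------
# assembled texture vector (93 features per image/region)
# ---------------------------------------------------------------------------

TEXTURE_CLASS_SIZES = {
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}


def texture_feature_vector(
    image: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    voxel_volume: float = 1.0,
    firstorder_std: bool = False,
) -> dict[str, float]:
    """All intensity/texture features of one image restricted to one region.

    Returns 93 named values (``class|name``); 94 when ``firstorder_std``.
    """
    mask = mask.astype(bool)
    values = image[mask]
    disc, n_levels = discretize(image, mask, n_bins)
    n_vox = int(mask.sum())
    # tight-crop to the mask bounding box: all matrices depend only on
    # in-mask voxels, and smaller grids make the builders much cheaper
    nz = np.nonzero(mask)
    slices = tuple(slice(int(ix.min()), int(ix.max()) + 1) for ix in nz)
    disc = disc[slices]
    out: dict[str, float] = {}
    for name, val in firstorder_features(values, voxel_volume, n_bins, with_std=firstorder_std).items():
        out[f"firstorder|{name}"] = val
    for name, val in glcm_features(glcm_matrix(disc, n_levels)).items():
        out[f"glcm|{name}"] = val
    for name, val in glrlm_features(glrlm_matrix(disc, n_levels), n_vox).items():
        out[f"glrlm|{name}"] = val
    for name, val in glszm_features(glszm_matrix(disc, n_levels), n_vox).items():
        out[f"glszm|{name}"] = val
    for name, val in gldm_features(gldm_matrix(disc, n_levels)).items():
        out[f"gldm|{name}"] = val
    for name, val in ngtdm_features(*ngtdm_stats(disc, n_levels)).items():
        out[f"ngtdm|{name}"] = val
    return out
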