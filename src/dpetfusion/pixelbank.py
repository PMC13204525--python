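"""Vectorized per-pixel 2D feature bank for the ITH branch.

Computes, for every in-mask pixel of a slice, the same 104 features that
:func:`dpetfusion.ith.pixel_features_reference` computes window by window
(19 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM +
10 window-geometry shape features on the 3x3 mask-intersected
neighbourhood) — but batched across all windows at once. The per-window
reference path is the oracle in the test suite; this module must agree
with it to float precision.
"""

from __future__ import annotations

import numpy as np

EPS = np.finfo(np.float64).eps

# 3x3 frame cells, row-major; cell i sits at offset OFFSETS[i] from the center
OFFSETS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
N_CELLS = 9

_DIRECTIONS = [(0, 1), (1, -1), (1, 0), (1, 1)]


def _cell_index(dr: int, dc: int) -> int | None:
    if abs(dr) > 1 or abs(dc) > 1:
        return None
    return (dr + 1) * 3 + (dc + 1)


def _direction_pairs() -> list[tuple[int, int]]:
    pairs = []
    for d in _DIRECTIONS:
        for i, (r, c) in enumerate(OFFSETS):
            j = _cell_index(r + d[0], c + d[1])
            if j is not None:
                pairs.append((i, j))
    return pairs


def _neighbor_pairs() -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(N_CELLS)]
    for i, (r, c) in enumerate(OFFSETS):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = _cell_index(r + dr, c + dc)
                if j is not None:
                    adj[i].append(j)
    return adj


def _lines() -> list[tuple[int, ...]]:
    lines: list[tuple[int, ...]] = []
    lines += [(0, 1, 2), (3, 4, 5), (6, 7, 8)]  # rows
    lines += [(0, 3, 6), (1, 4, 7), (2, 5, 8)]  # columns
    lines += [(0, 4, 8), (1, 5), (3, 7), (2,), (6,)]  # down-right diagonals
    lines += [(2, 4, 6), (1, 3), (5, 7), (0,), (8,)]  # down-left diagonals
    return lines


PAIRS = _direction_pairs()
ADJACENCY = _neighbor_pairs()
LINES = _lines()


# ---------------------------------------------------------------------------
# window extraction and discretization
# ---------------------------------------------------------------------------


def extract_windows(image: np.ndarray, mask: np.ndarray):
    """Values/validity of the 3x3 neighbourhood of every in-mask pixel.

    Returns (pixels (N,2), vals (N,9) with NaN at invalid cells,
    valid (N,9) bool).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    mask = mask.astype(bool)
    pixels = np.argwhere(mask)
    pimg = np.pad(image.astype(np.float64), 1, constant_values=np.nan)
    pmask = np.pad(mask, 1, constant_values=False)
    wimg = sliding_window_view(pimg, (3, 3))
    wmask = sliding_window_view(pmask, (3, 3))
    vals = wimg[pixels[:, 0], pixels[:, 1]].reshape(-1, N_CELLS).copy()
    valid = wmask[pixels[:, 0], pixels[:, 1]].reshape(-1, N_CELLS).copy()
    vals[~valid] = np.nan
    return pixels, vals, valid


def discretize_windows(vals: np.ndarray, valid: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-window fixed-bin-count levels 1..n_bins (0 at invalid cells)."""
    lo = np.nanmin(vals, axis=1)
    hi = np.nanmax(vals, axis=1)
    span = hi - lo
    disc = np.zeros(vals.shape, dtype=np.int32)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.floor((vals - lo[:, None]) / span[:, None] * n_bins) + 1
    scaled = np.clip(scaled, 1, n_bins)
    const = span <= 0
    disc[valid] = np.where(
        np.broadcast_to(const[:, None], vals.shape)[valid], 1, scaled[valid]
    ).astype(np.int32)
    return disc


# ---------------------------------------------------------------------------
# batched matrices
# ---------------------------------------------------------------------------


def glcm_batch(disc: np.ndarray, n_bins: int) -> np.ndarray:
    n = disc.shape[0]
    P = np.zeros((n, n_bins, n_bins), dtype=np.float64)
    idx = np.arange(n)
    for a, b in PAIRS:
        va, vb = disc[:, a], disc[:, b]
        m = (va > 0) & (vb > 0)
        np.add.at(P, (idx[m], va[m] - 1, vb[m] - 1), 1.0)
    P = P + P.transpose(0, 2, 1)
    tot = P.sum(axis=(1, 2), keepdims=True)
    np.divide(P, tot, out=P, where=tot > 0)
    return P


def glrlm_batch(disc: np.ndarray, n_bins: int) -> np.ndarray:
    n = disc.shape[0]
    R = np.zeros((n, n_bins, 3), dtype=np.float64)
    idx = np.arange(n)

    def _add(level, length, m):
        np.add.at(R, (idx[m], level[m] - 1, length - 1), 1.0)

    for line in LINES:
        if len(line) == 1:
            va = disc[:, line[0]]
            _add(va, 1, va > 0)
        elif len(line) == 2:
            va, vb = disc[:, line[0]], disc[:, line[1]]
            eq = (va > 0) & (va == vb)
            _add(va, 2, eq)
            _add(va, 1, (va > 0) & ~eq)
            _add(vb, 1, (vb > 0) & ~eq)
        else:
            va, vb, vc = disc[:, line[0]], disc[:, line[1]], disc[:, line[2]]
            eq_ab = (va > 0) & (va == vb)
            eq_bc = (vb > 0) & (vb == vc)
            _add(va, 3, eq_ab & eq_bc)
            _add(va, 2, eq_ab & ~eq_bc)
            _add(vb, 2, eq_bc & ~eq_ab)
            _add(va, 1, (va > 0) & ~eq_ab)
            _add(vb, 1, (vb > 0) & ~eq_ab & ~eq_bc)
            _add(vc, 1, (vc > 0) & ~eq_bc)
    return R


def glszm_batch(disc: np.ndarray, n_bins: int) -> np.ndarray:
    n = disc.shape[0]
    valid = disc > 0
    lab = np.where(valid, np.arange(N_CELLS)[None, :], N_CELLS)
    for _ in range(8):  # min-label propagation over 8-connected equal cells
        for c in range(N_CELLS):
            for nb in ADJACENCY[c]:
                same = valid[:, c] & valid[:, nb] & (disc[:, c] == disc[:, nb])
                better = same & (lab[:, nb] < lab[:, c])
                lab[:, c] = np.where(better, lab[:, nb], lab[:, c])
    sizes = np.zeros((n, N_CELLS), dtype=np.int64)
    idx = np.arange(n)
    for c in range(N_CELLS):
        m = valid[:, c]
        np.add.at(sizes, (idx[m], lab[m, c]), 1)
    S = np.zeros((n, n_bins, N_CELLS), dtype=np.float64)
    for c in range(N_CELLS):
        root = valid[:, c] & (lab[:, c] == c)
        if root.any():
            np.add.at(
                S, (idx[root], disc[root, c] - 1, sizes[root, c] - 1), 1.0
            )
    return S


def gldm_batch(disc: np.ndarray, n_bins: int) -> np.ndarray:
    n = disc.shape[0]
    valid = disc > 0
    dep = np.zeros((n, N_CELLS), dtype=np.int64)
    for c in range(N_CELLS):
        for nb in ADJACENCY[c]:
            dep[:, c] += (valid[:, c] & valid[:, nb] & (disc[:, c] == disc[:, nb]))
    D = np.zeros((n, n_bins, N_CELLS), dtype=np.float64)
    idx = np.arange(n)
    for c in range(N_CELLS):
        m = valid[:, c]
        np.add.at(D, (idx[m], disc[m, c] - 1, dep[m, c]), 1.0)
    return D


def ngtdm_batch(disc: np.ndarray, n_bins: int):
    n = disc.shape[0]
    valid = disc > 0
    nb_sum = np.zeros((n, N_CELLS), dtype=np.float64)
    nb_cnt = np.zeros((n, N_CELLS), dtype=np.float64)
    for c in range(N_CELLS):
        for nb in ADJACENCY[c]:
            nb_sum[:, c] += np.where(valid[:, nb], disc[:, nb], 0.0)
            nb_cnt[:, c] += valid[:, nb]
    has_nb = valid & (nb_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(disc - nb_sum / nb_cnt)
    n_i = np.zeros((n, n_bins), dtype=np.float64)
    s_i = np.zeros((n, n_bins), dtype=np.float64)
    idx = np.arange(n)
    for c in range(N_CELLS):
        m = has_nb[:, c]
        np.add.at(n_i, (idx[m], disc[m, c] - 1), 1.0)
        np.add.at(s_i, (idx[m], disc[m, c] - 1), diff[m, c])
    tot = n_i.sum(axis=1, keepdims=True)
    p_i = np.divide(n_i, tot, out=np.zeros_like(n_i), where=tot > 0)
    return n_i, p_i, s_i


# ---------------------------------------------------------------------------
# batched feature formulas (order mirrors dpetfusion.texture exactly)
# ---------------------------------------------------------------------------


def _xlog2(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)


def firstorder_batch(vals: np.ndarray, n_bins: int) -> np.ndarray:
    counts = (~np.isnan(vals)).sum(axis=1).astype(float)
    mean = np.nanmean(vals, axis=1)
    var = np.nanvar(vals, axis=1)
    std = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.nanpercentile(vals, [10, 25, 50, 75, 90], axis=1)
    lo = np.nanmin(vals, axis=1)
    hi = np.nanmax(vals, axis=1)
    robust = (vals >= p10[:, None]) & (vals <= p90[:, None])
    rcount = robust.sum(axis=1).astype(float)
    rsum = np.where(robust, vals, 0.0).sum(axis=1)
    rmean = np.divide(rsum, rcount, out=np.zeros_like(rsum), where=rcount > 0)
    rmad = np.divide(
        np.where(robust, np.abs(vals - rmean[:, None]), 0.0).sum(axis=1),
        rcount,
        out=np.zeros_like(rsum),
        where=rcount > 0,
    )
    # fixed-bin-count histogram probabilities for entropy/uniformity
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = np.floor((vals - lo[:, None]) / span[:, None] * n_bins)
    lev = np.clip(lev, 0, n_bins - 1)
    const = span <= 0
    hist = np.zeros((vals.shape[0], n_bins))
    ok = ~np.isnan(vals)
    idx = np.arange(vals.shape[0])
    for c in range(vals.shape[1]):
        m = ok[:, c]
        levc = np.where(const, 0, np.nan_to_num(lev[:, c]))
        np.add.at(hist, (idx[m], levc[m].astype(int)), 1.0)
    p = hist / counts[:, None]
    entropy = -_xlog2(p).sum(axis=1)
    uniformity = (p**2).sum(axis=1)
    # same relative zero-std guard as the reference implementation
    nonconst = std > 1e-10 * np.maximum(np.abs(mean), 1.0)
    safe_std = np.where(nonconst, std, 1.0)
    z = (vals - mean[:, None]) / safe_std[:, None]
    skew = np.where(nonconst, np.nanmean(z**3, axis=1), 0.0)
    kurt = np.where(nonconst, np.nanmean(z**4, axis=1), 0.0)
    energy = np.nansum(vals**2, axis=1)
    feats = [
        energy,
        energy,  # TotalEnergy with unit pixel area
        entropy,
        lo,
        p10,
        p90,
        hi,
        mean,
        p50,
        p75 - p25,
        hi - lo,
        np.nanmean(np.abs(vals - mean[:, None]), axis=1),
        rmad,
        np.sqrt(energy / counts),
        skew,
        kurt,
        var,
        uniformity,
        std,
    ]
    return np.column_stack(feats)


def glcm_batch_features(P: np.ndarray) -> np.ndarray:
    n, L, _ = P.shape
    i = np.arange(1, L + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=2)
    mu = (i[None, :] * px).sum(axis=1)
    sigma2 = ((i[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)
    sigma = np.sqrt(sigma2)
    diff_masks = np.stack([(np.abs(ii - jj) == k) for k in range(L)]).astype(float)
    sum_masks = np.stack([((ii + jj) == k) for k in range(2, 2 * L + 1)]).astype(float)
    p_diff = np.einsum("nij,kij->nk", P, diff_masks)
    p_sum = np.einsum("nij,kij->nk", P, sum_masks)
    k_diff = np.arange(L, dtype=np.float64)
    k_sum = np.arange(2, 2 * L + 1, dtype=np.float64)
    joint_ent = -_xlog2(P).sum(axis=(1, 2))
    diff_avg = (k_diff[None, :] * p_diff).sum(axis=1)
    autoc = np.einsum("nij,ij->n", P, ii * jj)
    hx = -_xlog2(px).sum(axis=1)
    pxpy = px[:, :, None] * px[:, None, :]
    lg = np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)
    hxy1 = -(np.where(P > 0, P, 0.0) * lg).sum(axis=(1, 2))
    hxy2 = -_xlog2(pxpy).sum(axis=(1, 2))
    imc1 = np.where(hx > 0, (joint_ent - hxy1) / np.where(hx > 0, hx, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - joint_ent)), 0.0, None))
    # maximal correlation coefficient
    safe_px = np.maximum(px, EPS)
    Q = np.einsum("nik,njk->nij", P, P / safe_px[:, None, :]) / safe_px[:, :, None]
    Q[~np.isfinite(Q)] = 0.0
    eig = np.sort(np.abs(np.linalg.eigvals(Q)), axis=1)
    occupied = (px > 0).sum(axis=1)
    mcc = np.where(occupied < 2, 1.0, np.sqrt(np.maximum(eig[:, -2], 0.0)))
    corr = np.where(
        sigma > 0,
        (autoc - mu * mu) / np.where(sigma2 > 0, sigma2, 1.0),
        1.0,
    )
    t = (ii + jj)[None, :, :] - 2 * mu[:, None, None]
    offdiag = np.abs(ii - jj) > 0
    inv_var_w = np.zeros_like(ii)
    inv_var_w[offdiag] = 1.0 / (ii - jj)[offdiag] ** 2
    feats = [
        autoc,
        mu,
        (t**4 * P).sum(axis=(1, 2)),
        (t**3 * P).sum(axis=(1, 2)),
        (t**2 * P).sum(axis=(1, 2)),
        np.einsum("nij,ij->n", P, (ii - jj) ** 2),
        corr,
        diff_avg,
        -_xlog2(p_diff).sum(axis=1),
        ((k_diff[None, :] - diff_avg[:, None]) ** 2 * p_diff).sum(axis=1),
        np.einsum("nij,ij->n", P, 1.0 / (1.0 + np.abs(ii - jj))),
        np.einsum("nij,ij->n", P, 1.0 / (1.0 + (ii - jj) ** 2)),
        np.einsum("nij,ij->n", P, 1.0 / (1.0 + ((ii - jj) / L) ** 2)),
        np.einsum("nij,ij->n", P, 1.0 / (1.0 + np.abs(ii - jj) / L)),
        imc1,
        imc2,
        np.einsum("nij,ij->n", P, inv_var_w),
        (P**2).sum(axis=(1, 2)),
        joint_ent,
        mcc,
        P.max(axis=(1, 2)),
        (k_sum[None, :] * p_sum).sum(axis=1),
        -_xlog2(p_sum).sum(axis=1),
        ((ii[None] - mu[:, None, None]) ** 2 * P).sum(axis=(1, 2)),
    ]
    return np.column_stack(feats)


def _run_zone_batch(mat: np.ndarray, n_pix: np.ndarray) -> np.ndarray:
    n, L, J = mat.shape
    i = np.arange(1, L + 1, dtype=np.float64)
    j = np.arange(1, J + 1, dtype=np.float64)
    nr = mat.sum(axis=(1, 2))
    nr_safe = np.where(nr > 0, nr, 1.0)
    pg = mat.sum(axis=2)
    pj = mat.sum(axis=1)
    p = mat / nr_safe[:, None, None]
    mu_i = (i[None, :] * p.sum(axis=2)).sum(axis=1)
    mu_j = (j[None, :] * p.sum(axis=1)).sum(axis=1)
    feats = [
        (mat / j[None, None, :] ** 2).sum(axis=(1, 2)) / nr_safe,
        (mat * j[None, None, :] ** 2).sum(axis=(1, 2)) / nr_safe,
        (pg**2).sum(axis=1) / nr_safe,
        (pg**2).sum(axis=1) / nr_safe**2,
        (pj**2).sum(axis=1) / nr_safe,
        (pj**2).sum(axis=1) / nr_safe**2,
        nr / n_pix,
        (p * (i[None, :, None] - mu_i[:, None, None]) ** 2).sum(axis=(1, 2)),
        (p * (j[None, None, :] - mu_j[:, None, None]) ** 2).sum(axis=(1, 2)),
        -_xlog2(p).sum(axis=(1, 2)),
        (mat / i[None, :, None] ** 2).sum(axis=(1, 2)) / nr_safe,
        (mat * i[None, :, None] ** 2).sum(axis=(1, 2)) / nr_safe,
        (mat / (i[None, :, None] ** 2 * j[None, None, :] ** 2)).sum(axis=(1, 2)) / nr_safe,
        (mat * i[None, :, None] ** 2 / j[None, None, :] ** 2).sum(axis=(1, 2)) / nr_safe,
        (mat * j[None, None, :] ** 2 / i[None, :, None] ** 2).sum(axis=(1, 2)) / nr_safe,
        (mat * i[None, :, None] ** 2 * j[None, None, :] ** 2).sum(axis=(1, 2)) / nr_safe,
    ]
    return np.column_stack(feats)


def gldm_batch_features(D: np.ndarray) -> np.ndarray:
    n, L, J = D.shape
    i = np.arange(1, L + 1, dtype=np.float64)
    j = np.arange(1, J + 1, dtype=np.float64)  # dependence count + 1
    nz = D.sum(axis=(1, 2))
    nz_safe = np.where(nz > 0, nz, 1.0)
    p = D / nz_safe[:, None, None]
    pg = D.sum(axis=2)
    pd = D.sum(axis=1)
    mu_i = (i[None, :] * p.sum(axis=2)).sum(axis=1)
    mu_j = (j[None, :] * p.sum(axis=1)).sum(axis=1)
    feats = [
        (D / j[None, None, :] ** 2).sum(axis=(1, 2)) / nz_safe,
        (D * j[None, None, :] ** 2).sum(axis=(1, 2)) / nz_safe,
        (pg**2).sum(axis=1) / nz_safe,
        (pd**2).sum(axis=1) / nz_safe,
        (pd**2).sum(axis=1) / nz_safe**2,
        (p * (i[None, :, None] - mu_i[:, None, None]) ** 2).sum(axis=(1, 2)),
        (p * (j[None, None, :] - mu_j[:, None, None]) ** 2).sum(axis=(1, 2)),
        -_xlog2(p).sum(axis=(1, 2)),
        (D / i[None, :, None] ** 2).sum(axis=(1, 2)) / nz_safe,
        (D * i[None, :, None] ** 2).sum(axis=(1, 2)) / nz_safe,
        (D / (i[None, :, None] ** 2 * j[None, None, :] ** 2)).sum(axis=(1, 2)) / nz_safe,
        (D * i[None, :, None] ** 2 / j[None, None, :] ** 2).sum(axis=(1, 2)) / nz_safe,
        (D * j[None, None, :] ** 2 / i[None, :, None] ** 2).sum(axis=(1, 2)) / nz_safe,
        (D * i[None, :, None] ** 2 * j[None, None, :] ** 2).sum(axis=(1, 2)) / nz_safe,
    ]
    return np.column_stack(feats)


def ngtdm_batch_features(n_i: np.ndarray, p_i: np.ndarray, s_i: np.ndarray) -> np.ndarray:
    n, L = p_i.shape
    i = np.arange(1, L + 1, dtype=np.float64)
    present = p_i > 0
    ngp = present.sum(axis=1)
    ntot = n_i.sum(axis=1)
    coars_den = (p_i * s_i).sum(axis=1)
    coarseness = np.where(coars_den > 0, 1.0 / np.where(coars_den > 0, coars_den, 1.0), 1e6)
    pij = p_i[:, :, None] * p_i[:, None, :]
    dij2 = (i[:, None] - i[None, :]) ** 2
    multi = (ngp > 1) & (ntot > 0)
    denom_pairs = np.where(multi, ngp * (ngp - 1), 1.0)
    contrast = np.where(
        multi,
        ((pij * dij2[None]).sum(axis=(1, 2)) / denom_pairs)
        * (s_i.sum(axis=1) / np.where(ntot > 0, ntot, 1.0)),
        0.0,
    )
    ip = i[None, :] * p_i
    busy_den = np.abs(
        np.where(present[:, :, None], ip[:, :, None], 0.0)
        - np.where(present[:, None, :], ip[:, None, :], 0.0)
    )
    busy_den = (busy_den * (present[:, :, None] & present[:, None, :])).sum(axis=(1, 2))
    busyness = np.where(
        multi & (busy_den > 0),
        (p_i * s_i).sum(axis=1) / np.where(busy_den > 0, busy_den, 1.0),
        0.0,
    )
    pp = p_i[:, :, None] + p_i[:, None, :]
    pair_ok = present[:, :, None] & present[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            np.abs(i[None, :, None] - i[None, None, :])
            * (
                p_i[:, :, None] * s_i[:, :, None]
                + p_i[:, None, :] * s_i[:, None, :]
            )
            / np.where(pp > 0, pp, 1.0)
        )
    complexity = np.where(
        multi, (num * pair_ok).sum(axis=(1, 2)) / np.where(ntot > 0, ntot, 1.0), 0.0
    )
    s_tot = s_i.sum(axis=1)
    strength_num = (pp * (i[None, :, None] - i[None, None, :]) ** 2 * pair_ok).sum(axis=(1, 2))
    strength = np.where(multi & (s_tot > 0), strength_num / np.where(s_tot > 0, s_tot, 1.0), 0.0)
    return np.column_stack([coarseness, contrast, busyness, complexity, strength])


def shape_batch(valid: np.ndarray) -> np.ndarray:
    """Window-geometry shape features via the memoized pattern table."""
    from dpetfusion.ith import _window_shape_features

    patterns = (valid * (1 << np.arange(N_CELLS))[None, :]).sum(axis=1)
    uniq, inverse = np.unique(patterns, return_inverse=True)
    table = np.array([_window_shape_features(int(p)) for p in uniq])
    return table[inverse]


def pixel_feature_matrix(image: np.ndarray, mask: np.ndarray, n_bins: int = 8):
    """(pixels, 104-column feature matrix) for all in-mask pixels."""
    pixels, vals, valid = extract_windows(image, mask)
    disc = discretize_windows(vals, valid, n_bins)
    n_pix = valid.sum(axis=1).astype(float)
    blocks = [
        firstorder_batch(vals, n_bins),
        glcm_batch_features(glcm_batch(disc, n_bins)),
        _run_zone_batch(glrlm_batch(disc, n_bins), n_pix),
        _run_zone_batch(glszm_batch(disc, n_bins), n_pix),
        gldm_batch_features(gldm_batch(disc, n_bins)),
        ngtdm_batch_features(*ngtdm_batch(disc, n_bins)),
        shape_batch(valid),
    ]
    return pixels, np.concatenate(blocks, axis=1)
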