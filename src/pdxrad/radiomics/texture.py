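"""3-D texture matrices and their features.

All families operate on a "level volume": an integer array that is 0
outside the ROI and holds quantized grey levels 1..n_levels inside.
Directional families (GLCM, GLRLM) aggregate over the 13 unique 3-D
direction vectors by merging the per-direction matrices before feature
computation; zone and distance families use 26-connected components;
neighbourhood families use the full 26-neighbourhood.  Zone distances are
Chebyshev distances to the ROI border.

Features follow the standard IBSI definitions; quantities that are
undefined on the input (e.g. GLCM correlation of a constant ROI) are
returned as NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix", "glcm_features",
    "glrlm_matrix", "glrlm_features",
    "glszm_matrix", "glszm_features",
    "gldzm_matrix", "gldzm_features",
    "ngldm_matrix", "ngldm_features",
    "ngtdm_table", "ngtdm_features",
    "GLCM_FEATURES", "GLRLM_FEATURES", "GLSZM_FEATURES",
    "GLDZM_FEATURES", "NGLDM_FEATURES", "NGTDM_FEATURES",
]

# 13 unique direction vectors of the 26-neighbourhood (one per +/- pair)
DIRECTIONS_13 = np.array(
    [
        (0, 0, 1), (0, 1, 0), (1, 0, 0),
        (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)

_NEIGHBORS_26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ],
    dtype=np.int64,
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _crop(lvol: np.ndarray) -> np.ndarray:
    """Crop to the ROI bounding box (plus nothing; borders handled per family)."""
    idx = np.nonzero(lvol)
    if len(idx[0]) == 0:
        raise ValueError("empty ROI")
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)
    return lvol[sl]


def _offset_slices(shape, d):
    """Source/destination slice pairs for an offset d within one array."""
    src, dst = [], []
    for n, o in zip(shape, d):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(lvol: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence matrix merged over the 13 directions, normalized."""
    lvol = _crop(np.asarray(lvol, dtype=np.int64))
    c = np.zeros((n_levels, n_levels))
    for d in DIRECTIONS_13:
        src, dst = _offset_slices(lvol.shape, d)
        a = lvol[src]
        b = lvol[dst]
        ok = (a > 0) & (b > 0)
        if not ok.any():
            continue
        np.add.at(c, (a[ok] - 1, b[ok] - 1), 1.0)
    c = c + c.T  # symmetric: count both directions of each pair
    total = c.sum()
    if total == 0:
        raise ValueError("no co-occurring voxel pairs in ROI")
    return c / total


GLCM_FEATURES = (
    "joint_max", "joint_average", "joint_variance", "joint_entropy",
    "diff_average", "diff_variance", "diff_entropy",
    "sum_average", "sum_variance", "sum_entropy",
    "asm", "contrast", "dissimilarity",
    "inv_diff", "inv_diff_norm", "inv_diff_moment", "inv_diff_moment_norm",
    "inv_variance", "correlation", "autocorrelation",
    "cluster_tendency", "cluster_shade", "cluster_prominence",
    "imc1", "imc2",
)


def glcm_features(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((ii * p).sum())  # == mean of px since p is symmetric
    var_x = float(((i - mu) ** 2 * px).sum())
    nz = p > 0

    k_diff = np.arange(ng)
    pd = np.zeros(ng)
    np.add.at(pd, np.abs(ii - jj).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    ps = np.zeros(2 * ng - 1)
    np.add.at(ps, (ii + jj).ravel() - 2, p.ravel())

    da = float((k_diff * pd).sum())
    sa = float((k_sum * ps).sum())
    out: dict[str, float] = {
        "joint_max": float(p.max()),
        "joint_average": mu,
        "joint_variance": float(((ii - mu) ** 2 * p).sum()),
        "joint_entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "diff_average": da,
        "diff_variance": float(((k_diff - da) ** 2 * pd).sum()),
        "diff_entropy": float(-(pd[pd > 0] * np.log2(pd[pd > 0])).sum()),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * ps).sum()),
        "sum_entropy": float(-(ps[ps > 0] * np.log2(ps[ps > 0])).sum()),
        "asm": float((p**2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inv_diff": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inv_diff_norm": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "inv_diff_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inv_diff_moment_norm": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
    }
    out["inv_variance"] = float((pd[1:] / k_diff[1:] ** 2).sum())
    out["correlation"] = (
        (out["autocorrelation"] - mu * mu) / var_x if var_x > 0 else np.nan
    )
    # information measures of correlation
    hxy = out["joint_entropy"]
    outer = np.outer(px, px)
    oz = outer > 0
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hxy1 = float(-(p[nz & oz] * np.log2(outer[nz & oz])).sum())
    hxy2 = float(-(outer[oz] * np.log2(outer[oz])).sum())
    out["imc1"] = (hxy - hxy1) / hx if hx > 0 else np.nan
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else np.nan
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(lvol: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts (levels x run length) merged over the 13 directions."""
    lvol = _crop(np.asarray(lvol, dtype=np.int64))
    shape = lvol.shape
    runs: dict[tuple[int, int], int] = {}
    max_len = 1
    for d in DIRECTIONS_13:
        # a run starts where the predecessor along -d is absent or differs
        prev = np.zeros_like(lvol)
        src, dst = _offset_slices(shape, d)
        prev[dst] = lvol[src]  # prev[v] = lvol[v - d]
        starts = np.argwhere((lvol > 0) & (prev != lvol))
        for z, y, x in starts:
            g = lvol[z, y, x]
            length = 1
            nz, ny, nx = z + d[0], y + d[1], x + d[2]
            while (
                0 <= nz < shape[0]
                and 0 <= ny < shape[1]
                and 0 <= nx < shape[2]
                and lvol[nz, ny, nx] == g
            ):
                length += 1
                nz += d[0]
                ny += d[1]
                nx += d[2]
            runs[(g, length)] = runs.get((g, length), 0) + 1
            max_len = max(max_len, length)
    mat = np.zeros((n_levels, max_len))
    for (g, length), cnt in runs.items():
        mat[g - 1, length - 1] = cnt
    return mat


GLRLM_FEATURES = (
    "sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
    "glnu", "glnu_norm", "rlnu", "rlnu_norm", "run_percentage",
    "gl_variance", "rl_variance", "run_entropy",
)


def _rl_style_features(mat: np.ndarray, n_voxels: int, prefix: tuple[str, ...]) -> dict[str, float]:
    """Shared feature arithmetic of the run/zone/distance families.

    ``mat`` rows are grey levels; columns run length, zone size or zone
    distance.  ``prefix`` carries the family-specific names in a fixed slot
    order (small-emphasis, large-emphasis, ... as in the *_FEATURES tuples).
    """
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty texture matrix")
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    r = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    rg = mat.sum(axis=1)  # per grey level
    rr = mat.sum(axis=0)  # per column index
    p = mat / ns
    mu_g = float((g * rg / ns).sum())
    mu_r = float((r * rr / ns).sum())
    nzp = p[p > 0]
    vals = {
        prefix[0]: float((rr / r**2).sum() / ns),
        prefix[1]: float((rr * r**2).sum() / ns),
        prefix[2]: float((rg / g**2).sum() / ns),
        prefix[3]: float((rg * g**2).sum() / ns),
        prefix[4]: float((mat / np.outer(g**2, r**2)).sum() / ns),
        prefix[5]: float((mat * np.outer(g**2, 1.0 / r**2)).sum() / ns),
        prefix[6]: float((mat * np.outer(1.0 / g**2, r**2)).sum() / ns),
        prefix[7]: float((mat * np.outer(g**2, r**2)).sum() / ns),
        prefix[8]: float((rg**2).sum() / ns),
        prefix[9]: float((rg**2).sum() / ns**2),
        prefix[10]: float((rr**2).sum() / ns),
        prefix[11]: float((rr**2).sum() / ns**2),
        prefix[12]: float(ns / n_voxels),
        prefix[13]: float((((g - mu_g) ** 2)[:, None] * p).sum()),
        prefix[14]: float((((r - mu_r) ** 2)[None, :] * p).sum()),
        prefix[15]: float(-(nzp * np.log2(nzp)).sum()),
    }
    return vals


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_style_features(mat, n_voxels, GLRLM_FEATURES)


# ---------------------------------------------------------------------------
# GLSZM / GLDZM
# ---------------------------------------------------------------------------

def _zones(lvol: np.ndarray, n_levels: int):
    """26-connected equal-level zones: yields (level, zone voxel indices)."""
    for g in range(1, n_levels + 1):
        labeled, nz = ndimage.label(lvol == g, structure=_STRUCT_26)
        for z in range(1, nz + 1):
            yield g, np.nonzero(labeled == z)


def glszm_matrix(lvol: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts (levels x zone size) for 26-connected equal-level zones."""
    lvol = _crop(np.asarray(lvol, dtype=np.int64))
    zones = [(g, len(idx[0])) for g, idx in _zones(lvol, n_levels)]
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size))
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


GLSZM_FEATURES = (
    "sze", "lze", "lgze", "hgze", "szlge", "szhge", "lzlge", "lzhge",
    "glnu", "glnu_norm", "zsnu", "zsnu_norm", "zone_percentage",
    "gl_variance", "zs_variance", "zs_entropy",
)


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_style_features(mat, n_voxels, GLSZM_FEATURES)


def gldzm_matrix(lvol: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone counts by (level, Chebyshev distance of the zone to the ROI border)."""
    lvol = _crop(np.asarray(lvol, dtype=np.int64))
    mask = lvol > 0
    # distance to outside the ROI; the volume edge counts as border (pad)
    dist = ndimage.distance_transform_cdt(np.pad(mask, 1), metric="chessboard")[
        tuple(slice(1, -1) for _ in range(3))
    ]
    entries = []
    for g, idx in _zones(lvol, n_levels):
        entries.append((g, int(dist[idx].min())))
    max_d = max(d for _, d in entries)
    mat = np.zeros((n_levels, max_d))
    for g, d in entries:
        mat[g - 1, d - 1] += 1
    return mat


GLDZM_FEATURES = (
    "sde", "lde", "lgze", "hgze", "sdlge", "sdhge", "ldlge", "ldhge",
    "glnu", "glnu_norm", "zdnu", "zdnu_norm", "zone_percentage",
    "gl_variance", "zd_variance", "zd_entropy",
)


def gldzm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_style_features(mat, n_voxels, GLDZM_FEATURES)


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_matrix(lvol: np.ndarray, n_levels: int) -> np.ndarray:
    """Dependence counts: rows grey level, column j = 1 + #equal 26-neighbours."""
    lvol = _crop(np.asarray(lvol, dtype=np.int64))
    dep = np.zeros(lvol.shape, dtype=np.int64)
    for d in _NEIGHBORS_26:
        src, dst = _offset_slices(lvol.shape, d)
        contrib = np.zeros(lvol.shape, dtype=np.int64)
        contrib[dst] = ((lvol[src] == lvol[dst]) & (lvol[src] > 0)).astype(np.int64)
        dep += contrib * (lvol > 0)
    mask = lvol > 0
    mat = np.zeros((n_levels, 27))
    np.add.at(mat, (lvol[mask] - 1, dep[mask]), 1.0)
    # trim trailing all-zero dependence columns
    last = int(np.max(np.nonzero(mat.sum(axis=0))[0]))
    return mat[:, : last + 1]


NGLDM_FEATURES = (
    "lde", "hde", "lgce", "hgce", "ldlge", "ldhge", "hdlge", "hdhge",
    "glnu", "dcnu", "gl_variance", "dc_variance", "dc_entropy", "dc_energy",
)


def ngldm_features(mat: np.ndarray) -> dict[str, float]:
    ns = mat.sum()
    if ns == 0:
        raise ValueError("empty dependence matrix")
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)  # dependence count
    sg = mat.sum(axis=1)
    sj = mat.sum(axis=0)
    p = mat / ns
    mu_g = float((g * sg / ns).sum())
    mu_j = float((j * sj / ns).sum())
    nzp = p[p > 0]
    return {
        "lde": float((sj / j**2).sum() / ns),
        "hde": float((sj * j**2).sum() / ns),
        "lgce": float((sg / g**2).sum() / ns),
        "hgce": float((sg * g**2).sum() / ns),
        "ldlge": float((mat / np.outer(g**2, j**2)).sum() / ns),
        "ldhge": float((mat * np.outer(g**2, 1.0 / j**2)).sum() / ns),
        "hdlge": float((mat * np.outer(1.0 / g**2, j**2)).sum() / ns),
        "hdhge": float((mat * np.outer(g**2, j**2)).sum() / ns),
        "glnu": float((sg**2).sum() / ns),
        "dcnu": float((sj**2).sum() / ns),
        "gl_variance": float((((g - mu_g) ** 2)[:, None] * p).sum()),
        "dc_variance": float((((j - mu_j) ** 2)[None, :] * p).sum()),
        "dc_entropy": float(-(nzp * np.log2(nzp)).sum()),
        "dc_energy": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(lvol: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-level occurrence counts n_g and tone differences s_g.

    ``s_g`` sums |g - mean of in-ROI 26-neighbours| over the ROI voxels of
    level g that have at least one in-ROI neighbour.
    """
    lvol = _crop(np.asarray(lvol, dtype=np.int64))
    mask = lvol > 0
    nbr_sum = np.zeros(lvol.shape)
    nbr_cnt = np.zeros(lvol.shape)
    for d in _NEIGHBORS_26:
        src, dst = _offset_slices(lvol.shape, d)
        nbr_sum[dst] += lvol[src] * (lvol[src] > 0)
        nbr_cnt[dst] += (lvol[src] > 0).astype(np.float64)
    valid = mask & (nbr_cnt > 0)
    nbar = np.zeros(lvol.shape)
    nbar[valid] = nbr_sum[valid] / nbr_cnt[valid]
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    gv = lvol[valid]
    dv = np.abs(lvol[valid].astype(np.float64) - nbar[valid])
    np.add.at(n, gv - 1, 1.0)
    np.add.at(s, gv - 1, dv)
    return n, s


NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")


def ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    nv = n.sum()
    if nv == 0:
        raise ValueError("empty neighbourhood tone table")
    p = n / nv
    present = p > 0
    g = np.arange(1, len(n) + 1, dtype=np.float64)
    ngp = int(present.sum())
    ps_dot = float((p * s).sum())

    out: dict[str, float] = {}
    out["coarseness"] = 1.0 / ps_dot if ps_dot > 0 else 1e6
    if ngp > 1:
        gi = g[present]
        pi = p[present]
        si = s[present]
        d2 = (gi[:, None] - gi[None, :]) ** 2
        out["contrast"] = float(
            (pi[:, None] * pi[None, :] * d2).sum()
            / (ngp * (ngp - 1))
            * (s.sum() / nv)
        )
        denom = float(np.abs(gi[:, None] * pi[:, None] - gi[None, :] * pi[None, :]).sum())
        out["busyness"] = ps_dot / denom if denom > 0 else 0.0
        psum = pi[:, None] + pi[None, :]
        out["complexity"] = float(
            (np.abs(gi[:, None] - gi[None, :])
             * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
             / psum).sum() / nv
        )
        out["strength"] = float((psum * d2).sum() / s.sum()) if s.sum() > 0 else 0.0
    else:
        out["contrast"] = 0.0
        out["busyness"] = 0.0
        out["complexity"] = 0.0
        out["strength"] = 0.0
    return out
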