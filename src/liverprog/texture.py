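"""IBSI-style radiomic feature bank computed from a masked 3D volume.

Implements the standard enabled-by-default 3D inventory: 14 shape, 18
first-order (intensity histogram) and 75 texture features from five
gray-level matrix families — co-occurrence (GLCM, 24), run length (GLRLM,
16), size zone (GLSZM, 16), dependence (GLDM, 14) and neighbouring gray
tone difference (NGTDM, 5) — 107 features per region.

Conventions:

* intensities are discretized with a fixed bin width (default 25 HU) from
  the ROI minimum, giving levels 1..Ng;
* GLCM and GLRLM use the 13 unique 3D direction offsets at distance 1;
  per-direction features are averaged;
* zones (GLSZM) and dependencies (GLDM, alpha = 0) use 26-connectivity;
* shape features are mesh-based (marching cubes at 0.5) with principal
  axis lengths from the physical-coordinate covariance.

Everything operates on the mask's bounding box, so cost scales with the
region, not the scan.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

__all__ = [
    "discretize",
    "shape_features",
    "firstorder_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "all_texture_features",
    "FEATURE_CLASS_COUNTS",
]

FEATURE_CLASS_COUNTS = {
    "shape": 14, "firstorder": 18, "glcm": 24,
    "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5,
}

_EPS = np.spacing(1.0)

# 13 unique direction offsets (z, y, x) covering all 26 neighbors up to sign
_DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1),
    (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
_NEIGHBORS26 = [d for d in _DIRECTIONS] + [tuple(-c for c in d) for d in _DIRECTIONS]


def _bbox_view(volume: np.ndarray, mask: np.ndarray):
    idx = np.where(mask)
    sl = tuple(slice(int(i.min()), int(i.max()) + 1) for i in idx)
    return volume[sl], mask[sl].astype(bool)


def discretize(volume: np.ndarray, mask: np.ndarray, bin_width: float = 25.0):
    """Fixed-bin-width discretization of in-mask intensities to levels 1..Ng."""
    vals = volume[mask]
    lo = np.floor(vals.min() / bin_width) * bin_width
    levels = np.floor((vals - lo) / bin_width).astype(np.int64) + 1
    disc = np.zeros(volume.shape, dtype=np.int64)
    disc[mask] = levels
    return disc, int(levels.max())


def _shift(arr: np.ndarray, d: tuple, fill=0):
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, off in enumerate(d):
        if off > 0:
            src[ax] = slice(off, None)
            dst[ax] = slice(None, -off)
        elif off < 0:
            src[ax] = slice(None, off)
            dst[ax] = slice(-off, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# shape (14)


def shape_features(mask: np.ndarray, spacing: tuple) -> dict:
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 1:
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))
    n_vox = int(mask.sum())

    # light smoothing before meshing suppresses the voxel staircase, which
    # otherwise overestimates the surface area of curved regions; very small
    # masks (smoothed peak below the iso level) fall back to the binary mesh
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2), 1.0)
    if padded.max() <= 0.5:
        padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))
    # mesh volume by divergence theorem over signed tetrahedra
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->", tri[:, 0],
                                      np.cross(tri[:, 1], tri[:, 2])) / 6.0))

    coords = np.column_stack(np.where(mask)).astype(float) * spacing
    centered = coords - coords.mean(axis=0)
    if n_vox > 1:
        cov = centered.T @ centered / n_vox
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()

    def _max_diam(pts: np.ndarray) -> float:
        pts = np.unique(pts, axis=0)
        if len(pts) < 2:
            return 0.0
        if len(pts) > 10 and pts.shape[1] >= 2:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass
        return float(pdist(pts).max())

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / max(area, _EPS)
    return {
        "shapeMeshVolume": mesh_volume,
        "shapeVoxelVolume": n_vox * voxel_volume,
        "shapeSurfaceArea": area,
        "shapeSurfaceVolumeRatio": area / max(mesh_volume, _EPS),
        "shapeSphericity": float(sphericity),
        "shapeMaximum3DDiameter": _max_diam(coords),
        "shapeMaximum2DDiameterSlice": _max_diam(coords[:, [1, 2]]),
        "shapeMaximum2DDiameterColumn": _max_diam(coords[:, [0, 2]]),
        "shapeMaximum2DDiameterRow": _max_diam(coords[:, [0, 1]]),
        "shapeMajorAxisLength": major,
        "shapeMinorAxisLength": minor,
        "shapeLeastAxisLength": least,
        "shapeElongation": float(np.sqrt(eig[1] / max(eig[0], _EPS))),
        "shapeFlatness": float(np.sqrt(eig[2] / max(eig[0], _EPS))),
    }


# ---------------------------------------------------------------------------
# first order (18)


def firstorder_features(volume: np.ndarray, mask: np.ndarray,
                        spacing: tuple, bin_width: float = 25.0) -> dict:
    x = volume[np.asarray(mask, dtype=bool)].astype(np.float64)
    n = x.size
    if n < 1:
        raise ValueError("empty mask")
    voxel_volume = float(np.prod(np.asarray(spacing, dtype=float)))
    mean = float(x.mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    var = float(x.var())
    sd = np.sqrt(var)
    inner = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))
    disc = np.floor((x - np.floor(x.min() / bin_width) * bin_width) / bin_width)
    _, counts = np.unique(disc, return_counts=True)
    p = counts / n
    if sd > 0:
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        skew, kurt = 0.0, 0.0
    return {
        "firstorderEnergy": energy,
        "firstorderTotalEnergy": energy * voxel_volume,
        "firstorderEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "firstorderMinimum": float(x.min()),
        "firstorder10Percentile": float(p10),
        "firstorder90Percentile": float(p90),
        "firstorderMaximum": float(x.max()),
        "firstorderMean": mean,
        "firstorderMedian": float(p50),
        "firstorderInterquartileRange": float(p75 - p25),
        "firstorderRange": float(x.max() - x.min()),
        "firstorderMeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "firstorderRobustMeanAbsoluteDeviation":
            float(np.mean(np.abs(inner - inner.mean()))) if inner.size else 0.0,
        "firstorderRootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorderSkewness": skew,
        "firstorderKurtosis": kurt,
        "firstorderVariance": var,
        "firstorderUniformity": float(np.sum(p**2)),
    }


# ---------------------------------------------------------------------------
# GLCM (24)


def _glcm_matrix(disc: np.ndarray, mask: np.ndarray, ng: int, d: tuple) -> np.ndarray:
    a = disc
    b = _shift(disc, d)
    valid = mask & _shift(mask, d)
    i, j = a[valid] - 1, b[valid] - 1
    P = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(P, (i, j), 1.0)
    P = P + P.T  # symmetric
    return P


def _glcm_single(P: np.ndarray) -> dict:
    ng = P.shape[0]
    s = P.sum()
    if s == 0:
        return {}
    p = P / s
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))  # symmetric: mu_x == mu_y
    sigma2 = float(np.sum((i - mu) ** 2 * px))
    sigma = np.sqrt(sigma2)

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(k_sum.size)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(k_diff.size)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    hx = -np.sum(px * np.log2(px + _EPS))
    hxy = -np.sum(p * np.log2(p + _EPS))
    pxy_prod = np.outer(px, px)
    hxy1 = -np.sum(p * np.log2(pxy_prod + _EPS))
    hxy2 = -np.sum(pxy_prod * np.log2(pxy_prod + _EPS))

    da = float(np.sum(k_diff * p_diff))
    contrast = float(np.sum((ii - jj) ** 2 * p))
    if sigma > _EPS:
        correlation = float((np.sum(ii * jj * p) - mu * mu) / sigma2)
    else:
        correlation = 1.0
    imc1 = float((hxy - hxy1) / max(hx, _EPS)) if hx > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii - jj)[off] ** 2)) if off.any() else 0.0

    # MCC: sqrt of second-largest eigenvalue of Q
    if ng > 1 and np.all(px > 0):
        Q = (p / px[:, None]) @ (p / px[:, None]).T
        eig = np.sort(np.linalg.eigvals(Q).real)
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size > 1 else 1.0
    elif ng > 1:
        keep = px > 0
        pk = p[np.ix_(keep, keep)]
        pxk = px[keep]
        if keep.sum() > 1:
            Q = (pk / pxk[:, None]) @ (pk / pxk[:, None]).T
            eig = np.sort(np.linalg.eigvals(Q).real)
            mcc = float(np.sqrt(max(0.0, eig[-2])))
        else:
            mcc = 1.0
    else:
        mcc = 1.0

    return {
        "glcmAutocorrelation": float(np.sum(ii * jj * p)),
        "glcmClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "glcmClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "glcmClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "glcmContrast": contrast,
        "glcmCorrelation": correlation,
        "glcmDifferenceAverage": da,
        "glcmDifferenceEntropy": float(-np.sum(p_diff * np.log2(p_diff + _EPS))),
        "glcmDifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "glcmId": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "glcmIdm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "glcmIdmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "glcmIdn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "glcmImc1": imc1,
        "glcmImc2": imc2,
        "glcmInverseVariance": inv_var,
        "glcmJointAverage": mu,
        "glcmJointEnergy": float(np.sum(p**2)),
        "glcmJointEntropy": float(hxy),
        "glcmMCC": mcc,
        "glcmMaximumProbability": float(p.max()),
        "glcmSumAverage": float(np.sum(k_sum * p_sum)),
        "glcmSumEntropy": float(-np.sum(p_sum * np.log2(p_sum + _EPS))),
        "glcmSumSquares": sigma2,
    }


def glcm_features(disc: np.ndarray, mask: np.ndarray, ng: int) -> dict:
    per_dir = []
    for d in _DIRECTIONS:
        P = _glcm_matrix(disc, mask, ng, d)
        if P.sum() > 0:
            per_dir.append(_glcm_single(P))
    if not per_dir:
        raise ValueError("mask too small for co-occurrence statistics")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM (16)


def _run_length_matrix(disc: np.ndarray, mask: np.ndarray, ng: int, d: tuple):
    """Run-length matrix P(level, length) along one direction.

    A run starts at a voxel with no same-level in-mask predecessor along
    ``-d``; its length is counted by intersecting cumulatively shifted
    copies of the voxel-to-successor connectivity map.
    """
    # conn[p] <=> p and p+d are both in the mask with the same level
    conn = mask & _shift(mask, d) & (disc == _shift(disc, d))
    back = tuple(-c for c in d)
    starts = mask & ~(_shift(mask, back) & (disc == _shift(disc, back)))
    max_len = max(disc.shape) + 1
    lengths = np.where(starts, 1, 0).astype(np.int64)
    cum = conn.copy()  # cum[p] <=> run covers p .. p+k*d
    k = 1
    while True:
        ext = starts & cum
        if not ext.any():
            break
        lengths[ext] += 1
        cum = cum & _shift(conn, tuple(c * k for c in d))
        k += 1
    P = np.zeros((ng, max_len), dtype=np.float64)
    zi = disc[starts] - 1
    li = np.clip(lengths[starts] - 1, 0, max_len - 1)
    np.add.at(P, (zi, li), 1.0)
    return P


def _rlm_features_single(P: np.ndarray, n_vox: int) -> dict:
    nr = P.sum()
    if nr == 0:
        return {}
    ng, nl = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    l = np.arange(1, nl + 1, dtype=np.float64)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    p = P / nr
    mu_i = float(np.sum(ii * p))
    mu_l = float(np.sum(ll * p))
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    return {
        "glrlmShortRunEmphasis": float(np.sum(P / ll**2) / nr),
        "glrlmLongRunEmphasis": float(np.sum(P * ll**2) / nr),
        "glrlmGrayLevelNonUniformity": float(np.sum(pg**2) / nr),
        "glrlmGrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nr**2),
        "glrlmRunLengthNonUniformity": float(np.sum(pr**2) / nr),
        "glrlmRunLengthNonUniformityNormalized": float(np.sum(pr**2) / nr**2),
        "glrlmRunPercentage": float(nr / n_vox),
        "glrlmGrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * p)),
        "glrlmRunVariance": float(np.sum((ll - mu_l) ** 2 * p)),
        "glrlmRunEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "glrlmLowGrayLevelRunEmphasis": float(np.sum(P / ii**2) / nr),
        "glrlmHighGrayLevelRunEmphasis": float(np.sum(P * ii**2) / nr),
        "glrlmShortRunLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ll**2)) / nr),
        "glrlmShortRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ll**2) / nr),
        "glrlmLongRunLowGrayLevelEmphasis": float(np.sum(P * ll**2 / ii**2) / nr),
        "glrlmLongRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 * ll**2) / nr),
    }


def glrlm_features(disc: np.ndarray, mask: np.ndarray, ng: int) -> dict:
    n_vox = int(mask.sum())
    per_dir = []
    for d in _DIRECTIONS:
        P = _run_length_matrix(disc, mask, ng, d)
        feats = _rlm_features_single(P, n_vox)
        if feats:
            per_dir.append(feats)
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM (16)


def _zone_matrix(disc: np.ndarray, mask: np.ndarray, ng: int):
    structure = np.ones((3, 3, 3), dtype=int)
    max_size = int(mask.sum())
    P = np.zeros((ng, max_size), dtype=np.float64)
    for level in np.unique(disc[mask]):
        lab, n = ndimage.label(disc == level, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for sz, cnt in zip(*np.unique(sizes, return_counts=True)):
            P[level - 1, sz - 1] += cnt
    return P


def glszm_features(disc: np.ndarray, mask: np.ndarray, ng: int) -> dict:
    P = _zone_matrix(disc, mask, ng)
    nz = P.sum()
    if nz == 0:
        raise ValueError("mask too small for zone statistics")
    n_vox = int(mask.sum())
    ngl, ns = P.shape
    i = np.arange(1, ngl + 1, dtype=np.float64)
    s = np.arange(1, ns + 1, dtype=np.float64)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = P / nz
    mu_i = float(np.sum(ii * p))
    mu_s = float(np.sum(ss * p))
    pg = P.sum(axis=1)
    pz = P.sum(axis=0)
    return {
        "glszmSmallAreaEmphasis": float(np.sum(P / ss**2) / nz),
        "glszmLargeAreaEmphasis": float(np.sum(P * ss**2) / nz),
        "glszmGrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "glszmGrayLevelNonUniformityNormalized": float(np.sum(pg**2) / nz**2),
        "glszmSizeZoneNonUniformity": float(np.sum(pz**2) / nz),
        "glszmSizeZoneNonUniformityNormalized": float(np.sum(pz**2) / nz**2),
        "glszmZonePercentage": float(nz / n_vox),
        "glszmGrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * p)),
        "glszmZoneVariance": float(np.sum((ss - mu_s) ** 2 * p)),
        "glszmZoneEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "glszmLowGrayLevelZoneEmphasis": float(np.sum(P / ii**2) / nz),
        "glszmHighGrayLevelZoneEmphasis": float(np.sum(P * ii**2) / nz),
        "glszmSmallAreaLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ss**2)) / nz),
        "glszmSmallAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ss**2) / nz),
        "glszmLargeAreaLowGrayLevelEmphasis": float(np.sum(P * ss**2 / ii**2) / nz),
        "glszmLargeAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 * ss**2) / nz),
    }


# ---------------------------------------------------------------------------
# GLDM (14), alpha = 0


def gldm_features(disc: np.ndarray, mask: np.ndarray, ng: int) -> dict:
    dep = np.zeros(disc.shape, dtype=np.int64)
    for d in _NEIGHBORS26:
        dep += (mask & _shift(mask, d) & (disc == _shift(disc, d))).astype(np.int64)
    dep = dep + 1  # dependence includes the center voxel
    nd_max = int(dep[mask].max())
    P = np.zeros((ng, nd_max), dtype=np.float64)
    np.add.at(P, (disc[mask] - 1, dep[mask] - 1), 1.0)
    nz = P.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nd_max + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = P / nz
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    return {
        "gldmSmallDependenceEmphasis": float(np.sum(P / jj**2) / nz),
        "gldmLargeDependenceEmphasis": float(np.sum(P * jj**2) / nz),
        "gldmGrayLevelNonUniformity": float(np.sum(pg**2) / nz),
        "gldmDependenceNonUniformity": float(np.sum(pd_**2) / nz),
        "gldmDependenceNonUniformityNormalized": float(np.sum(pd_**2) / nz**2),
        "gldmGrayLevelVariance": float(np.sum((ii - mu_i) ** 2 * p)),
        "gldmDependenceVariance": float(np.sum((jj - mu_j) ** 2 * p)),
        "gldmDependenceEntropy": float(-np.sum(p * np.log2(p + _EPS))),
        "gldmLowGrayLevelEmphasis": float(np.sum(P / ii**2) / nz),
        "gldmHighGrayLevelEmphasis": float(np.sum(P * ii**2) / nz),
        "gldmSmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * jj**2)) / nz),
        "gldmSmallDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 / jj**2) / nz),
        "gldmLargeDependenceLowGrayLevelEmphasis": float(np.sum(P * jj**2 / ii**2) / nz),
        "gldmLargeDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 * jj**2) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM (5)


def ngtdm_features(disc: np.ndarray, mask: np.ndarray, ng: int) -> dict:
    nbr_sum = np.zeros(disc.shape, dtype=np.float64)
    nbr_cnt = np.zeros(disc.shape, dtype=np.float64)
    for d in _NEIGHBORS26:
        valid = _shift(mask, d)
        nbr_sum += np.where(valid, _shift(disc, d).astype(np.float64), 0.0)
        nbr_cnt += valid.astype(np.float64)
    has_nbr = mask & (nbr_cnt > 0)
    abar = np.zeros(disc.shape)
    abar[has_nbr] = nbr_sum[has_nbr] / nbr_cnt[has_nbr]

    n_vp = int(has_nbr.sum())
    levels = disc[has_nbr]
    diffs = np.abs(levels - abar[has_nbr])
    n_i = np.bincount(levels - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(levels - 1, weights=diffs, minlength=ng)
    p_i = n_i / max(n_vp, 1)

    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)
    sum_ps = float(np.sum(p_i * s_i))
    sum_s = float(np.sum(s_i))

    coarseness = 1.0 / sum_ps if sum_ps > _EPS else 1e6
    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        iv, jv = np.meshgrid(i[present], i[present], indexing="ij")
        si_, sj_ = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        contrast = float(np.sum(pi_ * pj_ * (iv - jv) ** 2) / (ngp * (ngp - 1))
                         * sum_s / max(n_vp, 1))
        denom = float(np.sum(np.abs(iv * pi_ - jv * pj_)))
        busyness = sum_ps / denom if denom > _EPS else 0.0
        complexity = float(np.sum(np.abs(iv - jv)
                                  * (pi_ * si_ + pj_ * sj_) / (pi_ + pj_)) / max(n_vp, 1))
        strength = (float(np.sum((pi_ + pj_) * (iv - jv) ** 2)) / sum_s
                    if sum_s > _EPS else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdmCoarseness": coarseness,
        "ngtdmContrast": contrast,
        "ngtdmBusyness": busyness,
        "ngtdmComplexity": complexity,
        "ngtdmStrength": strength,
    }


# ---------------------------------------------------------------------------


def all_texture_features(volume: np.ndarray, mask: np.ndarray,
                         bin_width: float = 25.0) -> dict:
    """All 75 texture features (GLCM+GLRLM+GLSZM+GLDM+NGTDM) for one region."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask smaller than 2 voxels: texture undefined")
    vol_b, mask_b = _bbox_view(np.asarray(volume, dtype=np.float64), mask)
    disc, ng = discretize(vol_b, mask_b, bin_width)
    out = {}
    out.update(glcm_features(disc, mask_b, ng))
    out.update(glrlm_features(disc, mask_b, ng))
    out.update(glszm_features(disc, mask_b, ng))
    out.update(gldm_features(disc, mask_b, ng))
    out.update(ngtdm_features(disc, mask_b, ng))
    return out
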