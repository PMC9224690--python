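"""Texture-feature formulas ("original" 3D radiomics definitions).

Each public function maps raw count matrices from
:mod:`camrad.features.matrices` to the named feature dictionaries.  GLCM
and GLRLM features are computed per direction and averaged over the 13
directions; GLSZM and GLDM have a single matrix.  Grey-level values ``i``
are the integer bin values (1..n_bins); ``Ng`` in the normalized inverse
difference formulas counts the *distinct grey levels present* in the
region, matching the reference implementations.

Degenerate regions (single grey level, single voxel) produce finite values
throughout: entropies of one-point distributions are 0, and correlation of
a flat region is defined as 1.
"""

from __future__ import annotations

import numpy as np

from .names import GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES

_EPS = np.spacing(1.0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def _weighted_var(values: np.ndarray, probs: np.ndarray) -> float:
    mu = float((values * probs).sum())
    return float(((values - mu) ** 2 * probs).sum())


# ---------------------------------------------------------------------------
# GLCM


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric co-occurrence matrix."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    present = int((px > 0).sum())  # Ng: distinct levels present
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = np.sqrt(_weighted_var(i, px))
    sy = np.sqrt(_weighted_var(i, py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # p_{x+y}: k = 2..2Ng ; p_{x-y}: k = 0..Ng-1
    ksum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, P.ravel())
    kdiff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())

    hx = _entropy(px)
    hy = _entropy(py)
    hxy = _entropy(P.ravel())
    pxpy = np.outer(px, py)
    nz = P > 0
    hxy1 = float(-(P[nz] * np.log2(pxpy[nz] + _EPS)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    if sx * sy > 0:
        correlation = float(((ii * jj * P).sum() - ux * uy) / (sx * sy))
    else:
        correlation = 1.0
    da = float((kdiff * p_diff).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    imc2 = float(np.sqrt(imc2_arg)) if imc2_arg > 0 else 0.0
    inv_var = float((p_diff[1:] / kdiff[1:] ** 2).sum()) if ng > 1 else 0.0

    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "ClusterProminence": float(((ii + jj - ux - uy) ** 4 * P).sum()),
        "ClusterShade": float(((ii + jj - ux - uy) ** 3 * P).sum()),
        "ClusterTendency": float(((ii + jj - ux - uy) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(((kdiff - da) ** 2 * p_diff).sum()),
        "Id": float((p_diff / (1.0 + kdiff)).sum()),
        "Idm": float((p_diff / (1.0 + kdiff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (kdiff / present) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + kdiff / present)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": ux,
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MaximumProbability": float(P.max()),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": float(((ii - ux) ** 2 * P).sum()),
    }


def glcm_features_from_counts(counts: np.ndarray) -> dict[str, float]:
    """Direction-averaged GLCM features from (13, Ng, Ng) count matrices.

    Directions that produced no voxel pairs (possible for very small
    regions) are excluded from the average.
    """
    per_dir = []
    for C in counts:
        total = C.sum()
        if total > 0:
            per_dir.append(_glcm_single(C / total))
    if not per_dir:
        per_dir = [{name: 0.0 for name in GLCM_NAMES}]
    out = {name: float(np.mean([d[name] for d in per_dir])) for name in GLCM_NAMES}
    return out


# ---------------------------------------------------------------------------
# GLRLM


def _glrlm_single(R: np.ndarray, n_voxels: int) -> dict[str, float] | None:
    nr = R.sum()
    if nr == 0:
        return None
    ng, nl = R.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, nl + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    p = R / nr
    pg = R.sum(axis=1)  # per grey level
    pr = R.sum(axis=0)  # per run length
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "GrayLevelVariance": _weighted_var(ii.ravel(), p.ravel()),
        "HighGrayLevelRunEmphasis": float((R * ii**2).sum() / nr),
        "LongRunEmphasis": float((R * jj**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * ii**2 * jj**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * jj**2 / ii**2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((R / ii**2).sum() / nr),
        "RunEntropy": _entropy(p.ravel()),
        "RunLengthNonUniformity": float((pr**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": _weighted_var(jj.ravel(), p.ravel()),
        "ShortRunEmphasis": float((R / jj**2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * ii**2 / jj**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (ii**2 * jj**2)).sum() / nr),
    }


def glrlm_features_from_counts(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    """Direction-averaged GLRLM features from (13, Ng, max_run) counts."""
    per_dir = [d for R in counts if (d := _glrlm_single(R, n_voxels))]
    if not per_dir:
        per_dir = [{name: 0.0 for name in GLRLM_NAMES}]
    return {name: float(np.mean([d[name] for d in per_dir])) for name in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM


def glszm_features_from_counts(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    """GLSZM features from the (Ng, max_size) zone count matrix."""
    ns = Z.sum()
    if ns == 0:
        return {name: 0.0 for name in GLSZM_NAMES}
    ng, nsz = Z.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    s = np.arange(1, nsz + 1, dtype=np.float64)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = Z / ns
    pg = Z.sum(axis=1)
    pz = Z.sum(axis=0)
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / ns),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / ns**2),
        "GrayLevelVariance": _weighted_var(ii.ravel(), p.ravel()),
        "HighGrayLevelZoneEmphasis": float((Z * ii**2).sum() / ns),
        "LargeAreaEmphasis": float((Z * ss**2).sum() / ns),
        "LargeAreaHighGrayLevelEmphasis": float((Z * ii**2 * ss**2).sum() / ns),
        "LargeAreaLowGrayLevelEmphasis": float((Z * ss**2 / ii**2).sum() / ns),
        "LowGrayLevelZoneEmphasis": float((Z / ii**2).sum() / ns),
        "SizeZoneNonUniformity": float((pz**2).sum() / ns),
        "SizeZoneNonUniformityNormalized": float((pz**2).sum() / ns**2),
        "SmallAreaEmphasis": float((Z / ss**2).sum() / ns),
        "SmallAreaHighGrayLevelEmphasis": float((Z * ii**2 / ss**2).sum() / ns),
        "SmallAreaLowGrayLevelEmphasis": float((Z / (ii**2 * ss**2)).sum() / ns),
        "ZoneEntropy": _entropy(p.ravel()),
        "ZonePercentage": float(ns / n_voxels),
        "ZoneVariance": _weighted_var(ss.ravel(), p.ravel()),
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_features_from_counts(D: np.ndarray) -> dict[str, float]:
    """GLDM features from the (Ng, 27) dependence count matrix."""
    nz = D.sum()
    if nz == 0:
        return {name: 0.0 for name in GLDM_NAMES}
    ng, nd = D.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    d = np.arange(1, nd + 1, dtype=np.float64)
    ii, dd = np.meshgrid(i, d, indexing="ij")
    p = D / nz
    pg = D.sum(axis=1)
    pd = D.sum(axis=0)
    return {
        "DependenceEntropy": _entropy(p.ravel()),
        "DependenceNonUniformity": float((pd**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz**2),
        "DependenceVariance": _weighted_var(dd.ravel(), p.ravel()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelVariance": _weighted_var(ii.ravel(), p.ravel()),
        "HighGrayLevelEmphasis": float((D * ii**2).sum() / nz),
        "LargeDependenceEmphasis": float((D * dd**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((D * ii**2 * dd**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((D * dd**2 / ii**2).sum() / nz),
        "LowGrayLevelEmphasis": float((D / ii**2).sum() / nz),
        "SmallDependenceEmphasis": float((D / dd**2).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((D * ii**2 / dd**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((D / (ii**2 * dd**2)).sum() / nz),
    }
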