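"""Radiomic feature computation from a quantized ROI.

The default roster is 42 base features — Global (3), GLCM (8), GLRLM (13),
GLSZM (13), NGTDM (5) — plus six volume-normalized (VN) variants and the ROI
physical volume, for 49 names in total.  Global features are computed on the
continuous (pre-discretization) intensities inside the mask; all matrix
features use integer levels 1..G.

NGTDM Coarseness and Strength follow the Amadasun-King definitions; the
remaining matrix features follow the standard (IBSI-style) formulas with
merged-direction aggregation.
"""
from __future__ import annotations

import numpy as np

from .exceptions import DegenerateROIError
from .imaging import ImageVolume, ROIMask
from .matrices import TextureMatrices, build_texture_matrices
from .preprocessing import QuantizedROI

__all__ = [
    "GLOBAL_FEATURES",
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "NGTDM_FEATURES",
    "BASE_FEATURES",
    "VN_FEATURES",
    "ALL_FEATURES",
    "VOLUME_FEATURE",
    "extract_features",
    "volume_normalize",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]

_EPS = 1e-12

GLOBAL_FEATURES = ("Global Variance", "Global Skewness", "Global Kurtosis")
GLCM_FEATURES = tuple(
    f"GLCM {n}"
    for n in (
        "Energy",
        "Contrast",
        "Entropy",
        "Homogeneity",
        "Correlation",
        "SumAverage",
        "Variance",
        "Dissimilarity",
    )
)
GLRLM_FEATURES = tuple(
    f"GLRLM {n}"
    for n in (
        "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
        "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
    )
)
GLSZM_FEATURES = tuple(
    f"GLSZM {n}"
    for n in (
        "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
        "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
    )
)
NGTDM_FEATURES = tuple(
    f"NGTDM {n}" for n in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")
)
BASE_FEATURES = GLOBAL_FEATURES + GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES
VN_FEATURES = (
    "NGTDM Strength-VN",
    "NGTDM Busyness-VN",
    "NGTDM Coarseness-VN",
    "GLSZM GLN-VN",
    "GLRLM GLN-VN",
    "GLRLM RLN-VN",
)
VOLUME_FEATURE = "Prostate Volume"
ALL_FEATURES = BASE_FEATURES + VN_FEATURES + (VOLUME_FEATURE,)
assert len(BASE_FEATURES) == 42
assert len(ALL_FEATURES) == 49


def global_features(intensities: np.ndarray) -> dict[str, float]:
    """First-order statistics on raw in-mask intensities (population moments).

    Skewness and kurtosis are defined as 0 for a constant ROI; kurtosis is the
    plain (non-excess) fourth standardized moment.
    """
    x = np.asarray(intensities, dtype=np.float64)
    mu = x.mean()
    var = float(np.mean((x - mu) ** 2))
    if var < _EPS:
        return {"Global Variance": var, "Global Skewness": 0.0, "Global Kurtosis": 0.0}
    sd = np.sqrt(var)
    return {
        "Global Variance": var,
        "Global Skewness": float(np.mean(((x - mu) / sd) ** 3)),
        "Global Kurtosis": float(np.mean(((x - mu) / sd) ** 4)),
    }


def glcm_features(P: np.ndarray) -> dict[str, float]:
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=np.float64)
    I, J = np.meshgrid(i, i, indexing="ij")
    pi = P.sum(axis=1)  # marginal (equals column marginal by symmetry)
    mu = float((i * pi).sum())
    sigma2 = float(((i - mu) ** 2 * pi).sum())
    nz = P > 0
    if sigma2 < _EPS:
        corr = 0.0
    else:
        corr = float((((I - mu) * (J - mu) * P).sum()) / sigma2)
    return {
        "GLCM Energy": float((P**2).sum()),
        "GLCM Contrast": float(((I - J) ** 2 * P).sum()),
        "GLCM Entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "GLCM Homogeneity": float((P / (1.0 + np.abs(I - J))).sum()),
        "GLCM Correlation": corr,
        "GLCM SumAverage": float(((I + J) * P).sum()),
        "GLCM Variance": float(((I - mu) ** 2 * P).sum()),
        "GLCM Dissimilarity": float((np.abs(I - J) * P).sum()),
    }


def _run_zone_features(mat: np.ndarray, prefix: str, n_voxels: int, n_directions: int) -> dict:
    """Shared run-length / size-zone feature formulas.

    ``mat[g-1, l-1]`` counts runs (zones) of level g and length (size) l.
    The percentage feature normalizes by ``n_voxels * n_directions`` so it
    lies in (0, 1] for merged-direction run matrices (n_directions=1 for
    zones).
    """
    N = float(mat.sum())
    if N == 0:
        raise DegenerateROIError(f"{prefix}: empty matrix")
    g = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    l = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    Gm, Lm = np.meshgrid(g, l, indexing="ij")
    m = mat.astype(np.float64)
    p = m / N
    mu_g = float((Gm * p).sum())
    mu_l = float((Lm * p).sum())
    short, long_, low, high = (
        "SRE", "LRE", "LGRE", "HGRE") if prefix == "GLRLM" else ("SZE", "LZE", "LGZE", "HGZE")
    combos = ("SRLGE", "SRHGE", "LRLGE", "LRHGE") if prefix == "GLRLM" else (
        "SZLGE", "SZHGE", "LZLGE", "LZHGE")
    pct = ("RP", float(N / (n_voxels * n_directions))) if prefix == "GLRLM" else (
        "ZP", float(N / n_voxels))
    lvar = ("RLV", float(((Lm - mu_l) ** 2 * p).sum())) if prefix == "GLRLM" else (
        "ZSV", float(((Lm - mu_l) ** 2 * p).sum()))
    norm2 = ("RLN", float((m.sum(axis=0) ** 2).sum() / N)) if prefix == "GLRLM" else (
        "ZSN", float((m.sum(axis=0) ** 2).sum() / N))
    out = {
        short: float((m / Lm**2).sum() / N),
        long_: float((m * Lm**2).sum() / N),
        "GLN": float((m.sum(axis=1) ** 2).sum() / N),
        norm2[0]: norm2[1],
        pct[0]: pct[1],
        low: float((m / Gm**2).sum() / N),
        high: float((m * Gm**2).sum() / N),
        combos[0]: float((m / (Gm**2 * Lm**2)).sum() / N),
        combos[1]: float((m * Gm**2 / Lm**2).sum() / N),
        combos[2]: float((m * Lm**2 / Gm**2).sum() / N),
        combos[3]: float((m * Gm**2 * Lm**2).sum() / N),
        "GLV": float(((Gm - mu_g) ** 2 * p).sum()),
        lvar[0]: lvar[1],
    }
    return {f"{prefix} {k}": v for k, v in out.items()}


def glrlm_features(mat: np.ndarray, n_voxels: int, n_directions: int = 13) -> dict[str, float]:
    return _run_zone_features(mat, "GLRLM", n_voxels, n_directions)


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _run_zone_features(mat, "GLSZM", n_voxels, 1)


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    """Amadasun-King neighbourhood gray-tone difference features."""
    N = float(n_i.sum())
    if N == 0:
        raise DegenerateROIError("NGTDM: empty matrix")
    p = n_i / N
    present = np.nonzero(p > 0)[0]
    levels = (present + 1).astype(np.float64)
    pv, sv = p[present], s_i[present]
    Ngp = present.size
    psi = float((pv * sv).sum())
    coarseness = 1.0 / psi if psi > _EPS else 1.0 / _EPS

    if Ngp <= 1:
        return {
            "NGTDM Coarseness": coarseness,
            "NGTDM Contrast": 0.0,
            "NGTDM Busyness": 0.0,
            "NGTDM Complexity": 0.0,
            "NGTDM Strength": 0.0,
        }
    Pi, Pj = np.meshgrid(pv, pv, indexing="ij")
    Li, Lj = np.meshgrid(levels, levels, indexing="ij")
    contrast = float((Pi * Pj * (Li - Lj) ** 2).sum() / (Ngp * (Ngp - 1)) * (sv.sum() / N))
    denom_busy = float(np.abs(Li * Pi - Lj * Pj).sum())
    busyness = psi / denom_busy if denom_busy > _EPS else 0.0
    Si, Sj = np.meshgrid(pv * sv, pv * sv, indexing="ij")
    complexity = float((np.abs(Li - Lj) * (Si + Sj) / (N * (Pi + Pj))).sum())
    s_total = float(sv.sum())
    strength = float(((Pi + Pj) * (Li - Lj) ** 2).sum() / s_total) if s_total > _EPS else 0.0
    return {
        "NGTDM Coarseness": coarseness,
        "NGTDM Contrast": contrast,
        "NGTDM Busyness": busyness,
        "NGTDM Complexity": complexity,
        "NGTDM Strength": strength,
    }


def volume_normalize(fv: dict[str, float], n_voxels: int) -> dict[str, float]:
    """Fill the six volume-normalized variants.

    Division by voxel count for GLN/RLN/Strength/Busyness and multiplication
    for Coarseness (whose base value already grows with ROI size) are the
    documented defaults; the exact exponents live only in this function.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    out = dict(fv)
    out["GLSZM GLN-VN"] = fv["GLSZM GLN"] / n_voxels
    out["GLRLM GLN-VN"] = fv["GLRLM GLN"] / n_voxels
    out["GLRLM RLN-VN"] = fv["GLRLM RLN"] / n_voxels
    out["NGTDM Strength-VN"] = fv["NGTDM Strength"] / n_voxels
    out["NGTDM Busyness-VN"] = fv["NGTDM Busyness"] / n_voxels
    out["NGTDM Coarseness-VN"] = fv["NGTDM Coarseness"] * n_voxels
    return out


def extract_features(
    vol: ImageVolume, mask: ROIMask, q: QuantizedROI, matrices: TextureMatrices | None = None
) -> dict[str, float]:
    """Compute the full 49-name feature vector for one fraction.

    ``mask`` must be the final (cleaned / re-segmented) ROI matching ``q``;
    Global features use the raw intensities of ``vol`` inside it and
    ``Prostate Volume`` is its physical volume in cc.
    """
    if mask.shape != vol.shape:
        raise ValueError("mask is not aligned to the volume")
    if matrices is None:
        matrices = build_texture_matrices(q.levels, q.n_levels)
    fv: dict[str, float] = {}
    fv.update(global_features(vol.values[mask.values]))
    fv.update(glcm_features(matrices.glcm))
    fv.update(glrlm_features(matrices.glrlm, matrices.n_voxels, matrices.n_directions))
    fv.update(glszm_features(matrices.glszm, matrices.n_voxels))
    fv.update(ngtdm_features(matrices.ngtdm_n, matrices.ngtdm_s))
    fv = volume_normalize(fv, matrices.n_voxels)
    fv[VOLUME_FEATURE] = mask.volume_cc
    bad = [k for k, v in fv.items() if not np.isfinite(v)]
    if bad:
        raise DegenerateROIError(f"non-finite features: {bad}")
    return {name: fv[name] for name in ALL_FEATURES}
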