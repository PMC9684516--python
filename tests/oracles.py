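"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit loops, flood fills, pair
counting) and shares no code with the package implementation.
"""
from __future__ import annotations

import numpy as np

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]
OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(levels, i, j, k):
    return (
        0 <= i < levels.shape[0]
        and 0 <= j < levels.shape[1]
        and 0 <= k < levels.shape[2]
        and levels[i, j, k] > 0
    )


def glcm_oracle(levels: np.ndarray, G: int) -> np.ndarray:
    """Symmetric merged GLCM by explicit pair enumeration, normalized."""
    mat = np.zeros((G, G), dtype=np.float64)
    for i in range(levels.shape[0]):
        for j in range(levels.shape[1]):
            for k in range(levels.shape[2]):
                if levels[i, j, k] == 0:
                    continue
                for (dx, dy, dz) in OFFSETS_26:
                    a, b, c = i + dx, j + dy, k + dz
                    if _inside(levels, a, b, c):
                        mat[levels[i, j, k] - 1, levels[a, b, c] - 1] += 1
    total = mat.sum()
    return mat / total if total else mat


def glrlm_oracle(levels: np.ndarray, G: int) -> np.ndarray:
    """Run-length counts by walking each line voxel by voxel."""
    max_run = max(levels.shape)
    mat = np.zeros((G, max_run), dtype=np.int64)
    for (dx, dy, dz) in OFFSETS_13:
        for i in range(levels.shape[0]):
            for j in range(levels.shape[1]):
                for k in range(levels.shape[2]):
                    g = levels[i, j, k]
                    if g == 0:
                        continue
                    # run start: predecessor missing or different
                    pi, pj, pk = i - dx, j - dy, k - dz
                    if _inside(levels, pi, pj, pk) and levels[pi, pj, pk] == g:
                        continue
                    length = 1
                    a, b, c = i + dx, j + dy, k + dz
                    while _inside(levels, a, b, c) and levels[a, b, c] == g:
                        length += 1
                        a, b, c = a + dx, b + dy, c + dz
                    mat[g - 1, length - 1] += 1
    return mat


def glszm_oracle(levels: np.ndarray, G: int) -> np.ndarray:
    """Zone sizes by flood fill with 26-connectivity."""
    seen = np.zeros(levels.shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    for i in range(levels.shape[0]):
        for j in range(levels.shape[1]):
            for k in range(levels.shape[2]):
                g = levels[i, j, k]
                if g == 0 or seen[i, j, k]:
                    continue
                stack = [(i, j, k)]
                seen[i, j, k] = True
                size = 0
                while stack:
                    x, y, z = stack.pop()
                    size += 1
                    for (dx, dy, dz) in OFFSETS_26:
                        a, b, c = x + dx, y + dy, z + dz
                        if _inside(levels, a, b, c) and not seen[a, b, c] and levels[a, b, c] == g:
                            seen[a, b, c] = True
                            stack.append((a, b, c))
                zones.append((g, size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((G, max_size), dtype=np.int64)
    for g, s in zones:
        mat[g - 1, s - 1] += 1
    return mat


def ngtdm_oracle(levels: np.ndarray, G: int) -> tuple[np.ndarray, np.ndarray]:
    n_i = np.zeros(G, dtype=np.int64)
    s_i = np.zeros(G, dtype=np.float64)
    for i in range(levels.shape[0]):
        for j in range(levels.shape[1]):
            for k in range(levels.shape[2]):
                g = levels[i, j, k]
                if g == 0:
                    continue
                nbrs = [
                    levels[i + dx, j + dy, k + dz]
                    for (dx, dy, dz) in OFFSETS_26
                    if _inside(levels, i + dx, j + dy, k + dz)
                ]
                if not nbrs:
                    continue
                n_i[g - 1] += 1
                s_i[g - 1] += abs(g - sum(nbrs) / len(nbrs))
    return n_i, s_i


def auc_oracle(scores, labels) -> float:
    """Exhaustive concordant/tied pair counting."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def lloyd_two_level_oracle(values: np.ndarray) -> float:
    """Optimal 2-level scalar quantizer MSE by exhaustive boundary search."""
    uniq = np.unique(values)
    best = np.inf
    for split in range(1, uniq.size):
        lo = values[values < uniq[split]]
        hi = values[values >= uniq[split]]
        mse = (np.sum((lo - lo.mean()) ** 2) + np.sum((hi - hi.mean()) ** 2)) / values.size
        best = min(best, mse)
    return best


# ------------------------------------------------------------------
# Naive feature formulas (independent re-implementation, explicit loops)
# ------------------------------------------------------------------

def glcm_features_oracle(P: np.ndarray) -> dict[str, float]:
    G = P.shape[0]
    out = {k: 0.0 for k in (
        "Energy", "Contrast", "Entropy", "Homogeneity", "SumAverage", "Dissimilarity")}
    pi = [sum(P[i, j] for j in range(G)) for i in range(G)]
    mu = sum((i + 1) * pi[i] for i in range(G))
    sig2 = sum((i + 1 - mu) ** 2 * pi[i] for i in range(G))
    var = 0.0
    corr_num = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            out["Energy"] += p * p
            out["Contrast"] += (i - j) ** 2 * p
            if p > 0:
                out["Entropy"] -= p * np.log2(p)
            out["Homogeneity"] += p / (1 + abs(i - j))
            out["SumAverage"] += (i + j + 2) * p
            out["Dissimilarity"] += abs(i - j) * p
            var += (i + 1 - mu) ** 2 * p
            corr_num += (i + 1 - mu) * (j + 1 - mu) * p
    out["Variance"] = var
    out["Correlation"] = corr_num / sig2 if sig2 > 1e-12 else 0.0
    return {f"GLCM {k}": v for k, v in out.items()}


def rl_features_oracle(mat: np.ndarray, n_voxels: int, n_directions: int) -> dict[str, float]:
    G, R = mat.shape
    N = mat.sum()
    out = {}
    out["SRE"] = sum(mat[g, l] / (l + 1) ** 2 for g in range(G) for l in range(R)) / N
    out["LRE"] = sum(mat[g, l] * (l + 1) ** 2 for g in range(G) for l in range(R)) / N
    out["GLN"] = sum(mat[g, :].sum() ** 2 for g in range(G)) / N
    out["RLN"] = sum(mat[:, l].sum() ** 2 for l in range(R)) / N
    out["RP"] = N / (n_voxels * n_directions)
    out["LGRE"] = sum(mat[g, l] / (g + 1) ** 2 for g in range(G) for l in range(R)) / N
    out["HGRE"] = sum(mat[g, l] * (g + 1) ** 2 for g in range(G) for l in range(R)) / N
    out["SRLGE"] = sum(
        mat[g, l] / ((g + 1) ** 2 * (l + 1) ** 2) for g in range(G) for l in range(R)) / N
    out["SRHGE"] = sum(
        mat[g, l] * (g + 1) ** 2 / (l + 1) ** 2 for g in range(G) for l in range(R)) / N
    out["LRLGE"] = sum(
        mat[g, l] * (l + 1) ** 2 / (g + 1) ** 2 for g in range(G) for l in range(R)) / N
    out["LRHGE"] = sum(
        mat[g, l] * (g + 1) ** 2 * (l + 1) ** 2 for g in range(G) for l in range(R)) / N
    mu_g = sum((g + 1) * mat[g, l] / N for g in range(G) for l in range(R))
    mu_l = sum((l + 1) * mat[g, l] / N for g in range(G) for l in range(R))
    out["GLV"] = sum((g + 1 - mu_g) ** 2 * mat[g, l] / N for g in range(G) for l in range(R))
    out["RLV"] = sum((l + 1 - mu_l) ** 2 * mat[g, l] / N for g in range(G) for l in range(R))
    return out


def ngtdm_features_oracle(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    N = n_i.sum()
    G = len(n_i)
    p = n_i / N
    present = [i for i in range(G) if p[i] > 0]
    Ngp = len(present)
    psi = sum(p[i] * s_i[i] for i in present)
    coarse = 1.0 / psi if psi > 1e-12 else 1e12
    if Ngp <= 1:
        return {
            "NGTDM Coarseness": coarse, "NGTDM Contrast": 0.0, "NGTDM Busyness": 0.0,
            "NGTDM Complexity": 0.0, "NGTDM Strength": 0.0,
        }
    contrast = (
        sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
        / (Ngp * (Ngp - 1))
        * (sum(s_i[i] for i in present) / N)
    )
    busy_den = sum(
        abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
    )
    busy = psi / busy_den if busy_den > 1e-12 else 0.0
    cplx = sum(
        abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (N * (p[i] + p[j]))
        for i in present
        for j in present
    )
    s_tot = sum(s_i[i] for i in present)
    strength = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present) / s_tot
        if s_tot > 1e-12
        else 0.0
    )
    return {
        "NGTDM Coarseness": coarse,
        "NGTDM Contrast": contrast,
        "NGTDM Busyness": busy,
        "NGTDM Complexity": cplx,
        "NGTDM Strength": strength,
    }
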