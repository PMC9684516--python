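"""Gray-level texture matrix construction (GLCM, GLRLM, GLSZM, NGTDM).

All builders are 3D and mask-aware: voxels with level 0 are outside the ROI
and never contribute.  GLCM and GLRLM aggregate the 13 unique direction
vectors at Chebyshev distance 1, merged across directions before any
normalization.  GLSZM zones and NGTDM neighbourhoods use 26-connectivity.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse import csgraph

from .exceptions import DegenerateROIError

__all__ = ["DIRECTIONS_13", "TextureMatrices", "build_texture_matrices"]

# the 13 unique 3D direction vectors (one per antipodal pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass(frozen=True)
class TextureMatrices:
    """Texture matrices for one quantized ROI.

    glcm:
        G x G symmetric joint probability matrix (sums to 1).
    glrlm:
        G x R run-length counts summed over the 13 directions.
    glszm:
        G x Z zone-size counts (26-connected zones).
    ngtdm_n / ngtdm_s:
        Per-level voxel counts and summed absolute differences from the
        mask-aware neighbourhood average.
    """

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    ngtdm_n: np.ndarray
    ngtdm_s: np.ndarray
    n_levels: int
    n_voxels: int
    n_directions: int = 13


def _crop_to_bbox(levels: np.ndarray) -> np.ndarray:
    idx = np.nonzero(levels > 0)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    return levels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]


def _pair_slices(shape, d):
    """Slices (a, b) such that arr[a] and arr[b] are offset by direction d."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step == 1:
            src.append(slice(0, n - 1))
            dst.append(slice(1, n))
        else:
            src.append(slice(1, n))
            dst.append(slice(0, n - 1))
    return tuple(src), tuple(dst)


def _glcm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    G = n_levels
    counts = np.zeros(G * G, dtype=np.float64)
    for d in DIRECTIONS_13:
        a, b = _pair_slices(levels.shape, d)
        la, lb = levels[a].ravel(), levels[b].ravel()
        ok = (la > 0) & (lb > 0)
        if not ok.any():
            continue
        code = (la[ok].astype(np.int64) - 1) * G + (lb[ok] - 1)
        counts += np.bincount(code, minlength=G * G)
    mat = counts.reshape(G, G)
    mat = mat + mat.T  # count each ordered pair both ways (symmetrization)
    total = mat.sum()
    if total == 0:
        raise DegenerateROIError("no co-occurring voxel pairs in ROI")
    return mat / total


def _glrlm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Run-length counts over 13 directions via per-line run encoding.

    Voxels are grouped into digital lines by projecting their index onto the
    direction vector; runs break where the line, adjacency, or level changes.
    """
    coords = np.argwhere(levels > 0)
    lv = levels[levels > 0].astype(np.int64)
    max_run = max(levels.shape) if coords.size else 1
    counts = np.zeros((n_levels, max_run), dtype=np.int64)
    for d in DIRECTIONS_13:
        dv = np.array(d)
        # step index along the line: use the first nonzero component (unit
        # magnitude), so t advances by exactly 1 per step for diagonals too
        axis = next(i for i, c in enumerate(d) if c != 0)
        t = coords[:, axis] * d[axis]
        anchor = coords - t[:, None] * dv
        order = np.lexsort((t, anchor[:, 2], anchor[:, 1], anchor[:, 0]))
        ts, ls = t[order], lv[order]
        an = anchor[order]
        same_line = np.all(an[1:] == an[:-1], axis=1)
        contiguous = ts[1:] == ts[:-1] + 1
        same_level = ls[1:] == ls[:-1]
        brk = np.nonzero(~(same_line & contiguous & same_level))[0] + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [ts.size]))
        run_len = ends - starts
        run_lvl = ls[starts]
        np.add.at(counts, (run_lvl - 1, run_len - 1), 1)
    return counts


def _glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """26-connected equal-level zones via one sparse connected-components
    pass (a per-level flood fill is quadratic in the number of gray levels).
    """
    n = levels.size
    flat = levels.ravel()
    idx = np.arange(n).reshape(levels.shape)
    rows, cols = [], []
    for d in DIRECTIONS_13:
        a, b = _pair_slices(levels.shape, d)
        la, lb = levels[a].ravel(), levels[b].ravel()
        ok = (la > 0) & (la == lb)
        if ok.any():
            rows.append(idx[a].ravel()[ok])
            cols.append(idx[b].ravel()[ok])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = c = np.empty(0, dtype=np.int64)
    graph = sparse.coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n, n))
    _, comp = csgraph.connected_components(graph, directed=False)
    in_mask = flat > 0
    zone_of = comp[in_mask]
    sizes_all = np.bincount(zone_of)
    zone_ids = np.nonzero(sizes_all)[0]
    level_of_zone = np.zeros(sizes_all.size, dtype=np.int64)
    level_of_zone[zone_of] = flat[in_mask]
    sizes = sizes_all[zone_ids]
    mat = np.zeros((n_levels, int(sizes.max())), dtype=np.int64)
    np.add.at(mat, (level_of_zone[zone_ids] - 1, sizes - 1), 1)
    return mat


def _ngtdm(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    in_mask = levels > 0
    kernel = np.ones((3, 3, 3), dtype=np.float64)
    kernel[1, 1, 1] = 0.0
    nb_sum = ndimage.correlate(levels.astype(np.float64) * in_mask, kernel, mode="constant")
    nb_cnt = ndimage.correlate(in_mask.astype(np.float64), kernel, mode="constant")
    valid = in_mask & (nb_cnt > 0.5)
    abar = np.zeros_like(nb_sum)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    diffs = np.abs(levels.astype(np.float64) - abar)
    n_i = np.zeros(n_levels, dtype=np.int64)
    s_i = np.zeros(n_levels, dtype=np.float64)
    lv = levels[valid] - 1
    np.add.at(n_i, lv, 1)
    np.add.at(s_i, lv, diffs[valid])
    return n_i, s_i


def build_texture_matrices(levels: np.ndarray, n_levels: int) -> TextureMatrices:
    """Build all four texture matrices from a 3D integer level grid
    (0 = outside ROI, 1..G inside).
    """
    levels = np.asarray(levels)
    n_vox = int((levels > 0).sum())
    if n_vox < 2:
        raise DegenerateROIError("texture matrices need at least 2 in-mask voxels")
    lv = _crop_to_bbox(levels)
    n_i, s_i = _ngtdm(lv, n_levels)
    return TextureMatrices(
        glcm=_glcm(lv, n_levels),
        glrlm=_glrlm(lv, n_levels),
        glszm=_glszm(lv, n_levels),
        ngtdm_n=n_i,
        ngtdm_s=s_i,
        n_levels=n_levels,
        n_voxels=n_vox,
    )
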