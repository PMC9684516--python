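"""ROI preprocessing: fiducial streak-artifact removal, 3-sigma re-segmentation
and gray-level quantization.

The per-fraction order used by the pipeline is: isotropic resampling ->
fiducial artifact removal -> optional re-segmentation -> quantization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateROIError
from .imaging import ImageVolume, ROIMask

__all__ = [
    "QuantizedROI",
    "ArtifactRemovalResult",
    "remove_fiducial_artifacts",
    "collewet_resegment",
    "quantize_uniform",
    "quantize_lloyd_max",
    "quantization_mse",
]


@dataclass(frozen=True)
class QuantizedROI:
    """Integer gray levels 1..G inside the ROI (0 outside) plus provenance.

    ``representatives[g-1]`` is the reconstruction value of level ``g``; the
    quantizer's mean-squared error is measured against these.
    """

    levels: np.ndarray
    n_levels: int
    quantizer: str
    representatives: np.ndarray
    collewet_applied: bool
    source_stats: tuple[float, float]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels)
        if lv.max(initial=0) > self.n_levels:
            raise ValueError("level exceeds n_levels")
        if not (lv > 0).any():
            raise ValueError("quantized ROI is empty")
        object.__setattr__(self, "levels", lv.astype(np.int32))

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def n_voxels(self) -> int:
        return int((self.levels > 0).sum())


@dataclass(frozen=True)
class ArtifactRemovalResult:
    cleaned_mask: ROIMask
    removed_fraction: float
    threshold_range: tuple[float, float]


def _roi_stats(values: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    vals = values[mask]
    # population (n) denominator throughout, matching the re-segmentation convention
    return float(vals.mean()), float(vals.std())


def _bresenham_2d(x0: int, y0: int, x1: int, y1: int) -> list[tuple[int, int]]:
    """Integer line rasterization between two pixels (inclusive)."""
    pts = []
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx - dy
    x, y = x0, y0
    while True:
        pts.append((x, y))
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 > -dy:
            err -= dy
            x += sx
        if e2 < dx:
            err += dx
            y += sy
    return pts


def remove_fiducial_artifacts(
    vol: ImageVolume,
    mask: ROIMask,
    fiducial_centers_mm: list[tuple[float, float, float]],
    radius_mm: float = 5.0,
    fiducial_length_mm: float = 5.0,
) -> ArtifactRemovalResult:
    """Remove bright streak artifacts around implanted fiducial markers.

    The intensity threshold range ``[mu - 3 sigma, mu + 3 sigma]`` is estimated
    from ROI voxels on axial layers that contain no fiducial.  On fiducial
    layers, ROI voxels inside a ``radius_mm`` circle around each marker whose
    intensity falls outside the range are removed, together with straight
    pixel lines from each such voxel back to the marker centre (streak
    spokes).  Voxels on non-fiducial layers are never removed.
    """
    if mask.shape != vol.shape:
        raise ValueError("mask is not aligned to the volume")
    m = mask.values
    n_total = int(m.sum())
    if n_total == 0:
        raise DegenerateROIError("empty ROI")
    if not fiducial_centers_mm:
        return ArtifactRemovalResult(mask, 0.0, (float("nan"), float("nan")))

    sx, sy, sz = vol.spacing_mm
    nz = vol.shape[2]
    z_coords = np.arange(nz) * sz
    fid_layers = np.zeros(nz, dtype=bool)
    half = fiducial_length_mm / 2.0
    for (_, _, cz) in fiducial_centers_mm:
        # a layer is a fiducial layer if its slab intersects the rod extent
        fid_layers |= (z_coords + sz / 2.0 >= cz - half) & (z_coords - sz / 2.0 <= cz + half)

    clean_layer_mask = m & ~fid_layers[None, None, :]
    if not clean_layer_mask.any():
        raise DegenerateROIError("every axial layer contains a fiducial; threshold undefined")
    mu, sigma = _roi_stats(vol.values, clean_layer_mask)
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma

    out_of_range = (vol.values < lo) | (vol.values > hi)
    xs = np.arange(vol.shape[0])[:, None] * sx
    ys = np.arange(vol.shape[1])[None, :] * sy
    removed = np.zeros_like(m)
    for (cx, cy, cz) in fiducial_centers_mm:
        in_circle = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius_mm**2
        ci, cj = int(round(cx / sx)), int(round(cy / sy))
        for z in np.nonzero(fid_layers)[0]:
            hits = m[:, :, z] & in_circle & out_of_range[:, :, z]
            if not hits.any():
                continue
            removed[:, :, z] |= hits
            for (i, j) in zip(*np.nonzero(hits)):
                for (px, py) in _bresenham_2d(int(i), int(j), ci, cj):
                    if 0 <= px < vol.shape[0] and 0 <= py < vol.shape[1] and m[px, py, z]:
                        removed[px, py, z] = True

    cleaned = ROIMask(m & ~removed, mask.spacing_mm, mask.origin_mm)
    return ArtifactRemovalResult(cleaned, float(removed.sum()) / n_total, (lo, hi))


def collewet_resegment(vol: ImageVolume, mask: ROIMask) -> ROIMask:
    """Re-segment the ROI to voxels within ``[mu - 3 sigma, mu + 3 sigma]`` of
    its own intensity distribution (IBSI RS:3sigma).  Constant ROIs (sigma=0)
    are returned unchanged.  Not idempotent in general: removing voxels shifts
    mu and sigma, so a second application can remove further voxels.
    """
    if mask.shape != vol.shape:
        raise ValueError("mask is not aligned to the volume")
    if mask.voxel_count < 2:
        raise DegenerateROIError("re-segmentation needs at least 2 ROI voxels")
    mu, sigma = _roi_stats(vol.values, mask.values)
    if sigma == 0.0:
        return mask
    keep = mask.values & (vol.values >= mu - 3.0 * sigma) & (vol.values <= mu + 3.0 * sigma)
    return ROIMask(keep, mask.spacing_mm, mask.origin_mm)


def _quantized(levels, n_levels, quantizer, reps, collewet, vol, mask) -> QuantizedROI:
    mu, sigma = _roi_stats(vol.values, mask.values)
    return QuantizedROI(
        levels=levels,
        n_levels=n_levels,
        quantizer=quantizer,
        representatives=np.asarray(reps, dtype=np.float64),
        collewet_applied=collewet,
        source_stats=(mu, sigma),
        spacing_mm=vol.spacing_mm,
    )


def quantize_uniform(
    vol: ImageVolume, mask: ROIMask, n_levels: int = 256, collewet_applied: bool = False
) -> QuantizedROI:
    """Fixed-bin-number discretization: G equal-width bins from the ROI minimum
    to maximum; bins are half-open ``[lo, hi)`` with the top bin closed, so the
    minimum maps to level 1 and the maximum to level G.
    """
    if mask.voxel_count == 0:
        raise DegenerateROIError("empty ROI")
    vals = vol.values[mask.values]
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask.values] = 1
        reps = np.array([vmin])
    else:
        q = np.floor(n_levels * (vol.values - vmin) / (vmax - vmin)).astype(np.int32) + 1
        levels[mask.values] = np.minimum(q[mask.values], n_levels)
        width = (vmax - vmin) / n_levels
        reps = vmin + (np.arange(n_levels) + 0.5) * width
    return _quantized(levels, n_levels, "uniform", reps, collewet_applied, vol, mask)


def quantize_lloyd_max(
    vol: ImageVolume,
    mask: ROIMask,
    n_levels: int = 256,
    tol: float = 1e-7,
    max_iter: int = 500,
    collewet_applied: bool = False,
) -> QuantizedROI:
    """Lloyd-Max scalar quantization of the empirical ROI intensity
    distribution.

    Alternates (a) decision boundaries at midpoints of adjacent representative
    levels and (b) representatives at the conditional mean within each cell,
    starting from the uniform quantizer's partition; this makes the resulting
    mean-squared quantization error never worse than the uniform quantizer's.
    When the ROI has fewer distinct values than levels each distinct value
    gets its own level (zero error) and the remaining levels are unused.
    """
    if mask.voxel_count == 0:
        raise DegenerateROIError("empty ROI")
    vals = vol.values[mask.values]
    uniq, counts = np.unique(vals, return_counts=True)
    levels = np.zeros(vol.shape, dtype=np.int32)

    if uniq.size <= n_levels:
        lut = {v: g + 1 for g, v in enumerate(uniq)}
        idx = np.searchsorted(uniq, vol.values[mask.values])
        levels[mask.values] = idx + 1
        return _quantized(levels, n_levels, "lloyd_max", uniq, collewet_applied, vol, mask)

    vmin, vmax = float(uniq[0]), float(uniq[-1])
    boundaries = vmin + (vmax - vmin) * np.arange(1, n_levels) / n_levels
    w = counts.astype(np.float64)
    reps = None
    prev_mse = np.inf
    for _ in range(max_iter):
        cell = np.searchsorted(boundaries, uniq, side="right")
        sums = np.bincount(cell, weights=w * uniq, minlength=n_levels)
        wts = np.bincount(cell, weights=w, minlength=n_levels)
        new_reps = np.where(
            wts > 0, sums / np.where(wts > 0, wts, 1.0), reps if reps is not None else 0.0
        )
        if reps is not None:
            # empty cells keep their previous representative (stays sorted)
            new_reps = np.where(wts > 0, new_reps, reps)
        else:
            # first pass: seed empty cells with the uniform bin centre
            centres = vmin + (vmax - vmin) * (np.arange(n_levels) + 0.5) / n_levels
            new_reps = np.where(wts > 0, new_reps, centres)
        reps = new_reps
        mse = float(np.sum(w * (uniq - reps[cell]) ** 2) / w.sum())
        boundaries = 0.5 * (reps[:-1] + reps[1:])
        if prev_mse - mse < tol:
            break
        prev_mse = mse

    cell_full = np.searchsorted(boundaries, vol.values[mask.values], side="right")
    levels[mask.values] = cell_full.astype(np.int32) + 1
    return _quantized(levels, n_levels, "lloyd_max", reps, collewet_applied, vol, mask)


def quantization_mse(q: QuantizedROI, vol: ImageVolume) -> float:
    """Mean-squared error between ROI intensities and their reconstruction."""
    in_mask = q.levels > 0
    recon = q.representatives[q.levels[in_mask] - 1]
    return float(np.mean((vol.values[in_mask] - recon) ** 2))
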