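"""Seeded phantom-cohort generator.

Each synthetic patient carries a fractionation schedule, a latent binary
outcome, a per-fraction texture drift rate whose class separation is set by
``texture_effect_size``, toxicity events and IPSS scores correlated with the
latent outcome, and a deterministic per-fraction phantom volume: an
ellipsoidal ROI filled with band-limited speckle whose contrast grows and
autocorrelation length shrinks with fraction index at the drift rate.
Implanted fiducials appear as bright rods with radial streak spokes.

Cohorts are pure functions of (config, seed): every random draw comes from a
SeedSequence keyed by (master seed, patient index[, fraction index]), so
fractions can be generated lazily and in any order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .endpoints import GU_SYMPTOMS, ToxicityEvent
from .exceptions import ConfigurationError
from .imaging import ImageVolume, ROIMask, write_mask, write_volume
from .longitudinal import Schedule, compute_bed

__all__ = [
    "STRONG_EFFECT_SIZE",
    "CohortConfig",
    "PhantomParams",
    "FractionData",
    "SyntheticPatient",
    "generate_cohort",
    "generate_phantom_fraction",
    "write_cohort",
]

# documented "strong" drift-separation setting used by parameter-recovery tests
STRONG_EFFECT_SIZE = 3.0

_CLIP_SD = 2.8  # speckle is clipped here so no clean voxel exceeds mean + 3 sd
_FIDUCIAL_SD = 8.0  # rod intensity above ROI mean, in ROI sd units
_SPOKE_SD = 6.5
_SPOKE_LENGTH_MM = 4.0  # spokes stay inside the 5 mm removal circle


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort; see module docstring."""

    n_patients: int = 20
    schedules: tuple[tuple[float, int], ...] = ((80.0, 40), (70.2, 26))
    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing_mm: tuple[float, float, float] = (0.9, 0.9, 2.0)
    n_fiducials: int = 2
    texture_effect_size: float = 1.0
    outcome_prevalence: float = 0.5
    noise_style: str = "sharp"
    seed: int = 0
    roi_volume_cc: float = 40.0
    base_drift: float = 0.01
    drift_sd: float = 0.01
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not self.schedules:
            raise ConfigurationError("at least one schedule is required")
        for total, n in self.schedules:
            if n < 2:
                raise ConfigurationError("every schedule needs n_fractions >= 2")
            if total <= 0:
                raise ConfigurationError("total dose must be positive")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ConfigurationError("outcome prevalence must lie in (0, 1)")
        if self.texture_effect_size < 0:
            raise ConfigurationError("texture_effect_size must be >= 0")
        if self.noise_style not in ("sharp", "smooth"):
            raise ConfigurationError("noise_style must be 'sharp' or 'smooth'")
        if self.n_fiducials < 0:
            raise ConfigurationError("n_fiducials must be >= 0")
        if self.roi_volume_cc <= 0:
            raise ConfigurationError("roi_volume_cc must be positive")


@dataclass(frozen=True)
class PhantomParams:
    """Per-patient deterministic phantom parameters."""

    master_seed: int
    patient_index: int
    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    roi_center_mm: tuple[float, float, float]
    roi_semiaxes_mm: tuple[float, float, float]
    base_level: float
    amplitude: float
    corr_length_mm: float
    drift_rate: float
    fiducial_centers_mm: tuple[tuple[float, float, float], ...]
    fiducial_length_mm: float = 5.0
    noise_style: str = "sharp"


class FractionData(NamedTuple):
    volume: ImageVolume
    mask: ROIMask
    fiducial_centers_mm: tuple[tuple[float, float, float], ...]
    artifact_voxels: np.ndarray  # (M, 3) integer indices of injected artifact voxels


@dataclass
class SyntheticPatient:
    """One phantom patient; fraction volumes are generated on demand."""

    patient_id: str
    schedule: Schedule
    drift_rate: float
    latent_outcome: int
    toxicity_events: list[ToxicityEvent]
    ipss_initial: int
    ipss_final: int
    params: PhantomParams

    def get_fraction(self, fraction_index: int) -> FractionData:
        if not 1 <= fraction_index <= self.schedule.n_fractions:
            raise ValueError(f"fraction index outside 1..{self.schedule.n_fractions}")
        return generate_phantom_fraction(self.params, fraction_index)

    @property
    def fractions(self) -> list[FractionData]:
        """All fractions, eagerly materialized (memory grows with n)."""
        return [self.get_fraction(k) for k in range(1, self.schedule.n_fractions + 1)]


def _roi_geometry(config: CohortConfig) -> tuple[tuple, tuple]:
    extent = tuple(n * s for n, s in zip(config.grid_shape, config.voxel_spacing_mm))
    center = tuple(e / 2.0 for e in extent)
    vol_mm3 = config.roi_volume_cc * 1000.0
    # prolate ellipsoid with 1:1:1.2 axes
    r = (3.0 * vol_mm3 / (4.0 * np.pi * 1.2)) ** (1.0 / 3.0)
    semi = (r, r, 1.2 * r)
    for ax, (s, c, e) in enumerate(zip(semi, center, extent)):
        if c - s < 0 or c + s > e:
            raise ConfigurationError(
                f"ROI of {config.roi_volume_cc} cc does not fit the grid on axis {ax}"
            )
    return center, semi


def _ellipsoid_mask(grid_shape, spacing, center, semi) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    return (
        ((X - center[0]) / semi[0]) ** 2
        + ((Y - center[1]) / semi[1]) ** 2
        + ((Z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def generate_phantom_fraction(params: PhantomParams, fraction_index: int) -> FractionData:
    """Generate the phantom volume for one treatment fraction.

    Deterministic in (params, fraction_index).  Speckle contrast grows and
    correlation length shrinks linearly with fraction index at
    ``params.drift_rate``; the speckle is clipped at +-2.8 in-ROI standard
    deviations so that with no fiducials no voxel strays past mean + 3 sd.
    """
    if fraction_index < 1:
        raise ValueError("fraction_index must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([params.master_seed, params.patient_index, fraction_index])
    )
    spacing = params.spacing_mm
    mask_arr = _ellipsoid_mask(params.grid_shape, spacing, params.roi_center_mm, params.roi_semiaxes_mm)
    if not mask_arr.any():
        raise ConfigurationError("ROI is empty on this grid")

    growth = 1.0 + params.drift_rate * (fraction_index - 1)
    amp = params.amplitude * growth
    corr_mm = params.corr_length_mm / growth
    sigma_vox = [max(corr_mm / s, 1e-6) for s in spacing]

    noise = rng.standard_normal(params.grid_shape)
    speckle = gaussian_filter(noise, sigma=sigma_vox)
    if params.noise_style == "smooth":
        # emulates iterative reconstruction: extra spatial low-pass
        speckle = gaussian_filter(speckle, sigma=1.5)
    # centre on the ROI mean so the clip bound is symmetric about it
    speckle = (speckle - speckle[mask_arr].mean()) / speckle[mask_arr].std()
    speckle = np.clip(speckle, -_CLIP_SD, _CLIP_SD)
    values = params.base_level + amp * speckle

    artifact_idx: list[tuple[int, int, int]] = []
    for (cx, cy, cz) in params.fiducial_centers_mm:
        ci = int(round(cx / spacing[0]))
        cj = int(round(cy / spacing[1]))
        ck = int(round(cz / spacing[2]))
        half_layers = int(np.floor(params.fiducial_length_mm / 2.0 / spacing[2]))
        layers = [
            z for z in range(ck - half_layers, ck + half_layers + 1)
            if 0 <= z < params.grid_shape[2]
        ]
        spoke_px = int(round(_SPOKE_LENGTH_MM / spacing[0]))
        for z in layers:
            if mask_arr[ci, cj, z]:
                values[ci, cj, z] = params.base_level + _FIDUCIAL_SD * amp
                artifact_idx.append((ci, cj, z))
            for (di, dj) in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                for step in range(1, spoke_px + 1):
                    pi, pj = ci + di * step, cj + dj * step
                    if not (0 <= pi < params.grid_shape[0] and 0 <= pj < params.grid_shape[1]):
                        break
                    if mask_arr[pi, pj, z]:
                        values[pi, pj, z] = params.base_level + _SPOKE_SD * amp
                        artifact_idx.append((pi, pj, z))

    vol = ImageVolume(values, spacing)
    mask = ROIMask(mask_arr, spacing)
    art = np.array(sorted(set(artifact_idx)), dtype=np.int64).reshape(-1, 3)
    return FractionData(vol, mask, params.fiducial_centers_mm, art)


def _sample_fiducials(rng, config, center, semi) -> tuple[tuple[float, float, float], ...]:
    """Place fiducials inside the central half of the ROI, snapped to voxel
    centres so their physical coordinates are exactly representable."""
    spacing = config.voxel_spacing_mm
    out = []
    for _ in range(config.n_fiducials):
        while True:
            u = rng.uniform(-0.5, 0.5, size=3)
            if (u**2).sum() <= 0.25:
                break
        pos = [c + ui * s for c, ui, s in zip(center, u, semi)]
        idx = [int(round(p / sp)) for p, sp in zip(pos, spacing)]
        out.append(tuple(i * sp for i, sp in zip(idx, spacing)))
    return tuple(out)


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full phantom cohort for a configuration.

    Latent structure: outcome ~ Bernoulli(prevalence); drift rate ~
    Normal(base + effect * sd * outcome, sd) truncated at 0, so a zero effect
    size makes images independent of outcomes.  Toxicity events, post-RT
    events and the IPSS change are sampled conditionally on the outcome.
    """
    center, semi = _roi_geometry(config)
    patients: list[SyntheticPatient] = []
    for p in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, p]))
        total, n_fx = config.schedules[int(rng.integers(len(config.schedules)))]
        schedule = Schedule.from_total(total, n_fx, config.alpha_beta)
        total_bed = compute_bed(schedule)

        outcome = int(rng.random() < config.outcome_prevalence)
        drift = float(
            config.base_drift
            + config.texture_effect_size * config.drift_sd * outcome
            + rng.normal(0.0, config.drift_sd)
        )
        drift = max(drift, 0.0)

        events: list[ToxicityEvent] = []
        if outcome:
            grade = 2 + int(rng.random() < 0.3)
            symptom = GU_SYMPTOMS[int(rng.integers(len(GU_SYMPTOMS)))]
            onset = float(rng.uniform(0.0, total_bed))
            events.append(ToxicityEvent(symptom, grade, onset, "during_RT"))
        elif rng.random() < 0.4:
            symptom = GU_SYMPTOMS[int(rng.integers(len(GU_SYMPTOMS)))]
            events.append(
                ToxicityEvent(symptom, 1, float(rng.uniform(0.0, total_bed)), "during_RT")
            )
        p_post = 0.7 if outcome else 0.15
        if rng.random() < p_post:
            symptom = GU_SYMPTOMS[int(rng.integers(len(GU_SYMPTOMS)))]
            events.append(ToxicityEvent(symptom, 2, total_bed, "post_RT"))

        ipss_i = int(rng.integers(8, 26))
        improve = rng.random() < (0.25 if outcome else 0.75)
        magnitude = int(rng.integers(1, 9))
        delta = -magnitude if improve else magnitude
        ipss_f = int(np.clip(ipss_i + delta, 0, 35))

        params = PhantomParams(
            master_seed=config.seed,
            patient_index=p,
            grid_shape=config.grid_shape,
            spacing_mm=config.voxel_spacing_mm,
            roi_center_mm=center,
            roi_semiaxes_mm=semi,
            base_level=float(100.0 + rng.normal(0.0, 5.0)),
            amplitude=float(10.0 * np.exp(rng.normal(0.0, 0.1))),
            corr_length_mm=2.0,
            drift_rate=drift,
            fiducial_centers_mm=_sample_fiducials(rng, config, center, semi),
            noise_style=config.noise_style,
        )
        patients.append(
            SyntheticPatient(
                patient_id=f"P{p:03d}",
                schedule=schedule,
                drift_rate=drift,
                latent_outcome=outcome,
                toxicity_events=events,
                ipss_initial=ipss_i,
                ipss_final=ipss_f,
                params=params,
            )
        )
    return patients


def write_cohort(
    patients: list[SyntheticPatient],
    out_dir: str | Path,
    volume_format: str = "nrrd",
) -> Path:
    """Persist a cohort: per-fraction volumes/masks, a fiducial CSV in mm, and
    a JSON manifest of schedules, events and scores.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nrrd": ".nrrd", "nifti": ".nii"}[volume_format]
    manifest: dict = {"patients": []}
    fid_rows = ["patient_id,fiducial,x_mm,y_mm,z_mm"]
    for pt in patients:
        pdir = out_dir / pt.patient_id
        pdir.mkdir(exist_ok=True)
        for k in range(1, pt.schedule.n_fractions + 1):
            fx = pt.get_fraction(k)
            write_volume(fx.volume, pdir / f"fx{k:03d}{ext}")
            write_mask(fx.mask, pdir / f"fx{k:03d}_mask{ext}")
        for i, (x, y, z) in enumerate(pt.params.fiducial_centers_mm):
            fid_rows.append(f"{pt.patient_id},{i},{x!r},{y!r},{z!r}")
        manifest["patients"].append(
            {
                "patient_id": pt.patient_id,
                "n_fractions": pt.schedule.n_fractions,
                "dose_per_fraction": pt.schedule.dose_per_fraction,
                "alpha_beta": pt.schedule.alpha_beta,
                "drift_rate": pt.drift_rate,
                "latent_outcome": pt.latent_outcome,
                "ipss_initial": pt.ipss_initial,
                "ipss_final": pt.ipss_final,
                "toxicity_events": [
                    {
                        "gu_symptom": e.gu_symptom,
                        "grade": e.grade,
                        "onset_bed": e.onset_bed,
                        "phase": e.phase,
                    }
                    for e in pt.toxicity_events
                ],
            }
        )
    (out_dir / "fiducials.csv").write_text("\n".join(fid_rows) + "\n")
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
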