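"""Delta-feature computation, biologically effective dose (BED) arithmetic,
and BED-bin averaging into the modeling design matrix.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "Schedule",
    "DEFAULT_BINS",
    "compute_drf",
    "compute_bed",
    "cumulative_bed",
    "fractions_to_reach_bed",
    "assign_bin",
    "bin_drfs",
]

DEFAULT_BINS: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0, 100.0, 120.0)
RF1_EPS = 1e-12


@dataclass(frozen=True)
class Schedule:
    """A fractionation schedule: n fractions of d Gy each.

    ``alpha_beta`` is the linear-quadratic alpha/beta ratio in Gy (default 3,
    the prostate value used for BED alignment of mixed schedules).
    """

    n_fractions: int
    dose_per_fraction: float
    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ConfigurationError("schedule needs n_fractions >= 1")
        if self.dose_per_fraction <= 0:
            raise ConfigurationError("dose per fraction must be positive")
        if self.alpha_beta <= 0:
            raise ConfigurationError("alpha/beta must be positive")

    @classmethod
    def from_total(cls, total_dose: float, n_fractions: int, alpha_beta: float = 3.0) -> "Schedule":
        return cls(n_fractions, total_dose / n_fractions, alpha_beta)

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.dose_per_fraction


def compute_bed(schedule: Schedule) -> float:
    """Total BED = n * d * (1 + d / (alpha/beta)) in Gy."""
    d = schedule.dose_per_fraction
    return schedule.n_fractions * d * (1.0 + d / schedule.alpha_beta)


def cumulative_bed(schedule: Schedule, k: int) -> float:
    """BED accumulated after k delivered fractions (strictly increasing in k)."""
    if not 0 <= k <= schedule.n_fractions:
        raise ValueError(f"k={k} outside 0..{schedule.n_fractions}")
    d = schedule.dose_per_fraction
    return k * d * (1.0 + d / schedule.alpha_beta)


def fractions_to_reach_bed(schedule: Schedule, bed_target: float) -> int:
    """Smallest number of fractions whose cumulative BED reaches the target."""
    for k in range(1, schedule.n_fractions + 1):
        if cumulative_bed(schedule, k) >= bed_target:
            return k
    raise ValueError(f"schedule never accumulates {bed_target} Gy BED")


def compute_drf(rf_n: float, rf_1: float, eps: float = RF1_EPS) -> float:
    """Delta-radiomic feature: (RF_N - RF_1) / |RF_1|, guarded near zero."""
    if not (np.isfinite(rf_n) and np.isfinite(rf_1)):
        raise ValueError("feature values must be finite")
    return (rf_n - rf_1) / max(abs(rf_1), eps)


def assign_bin(
    schedule: Schedule, k: int, bins: tuple[float, ...] = DEFAULT_BINS
) -> float | None:
    """Bin of fraction k: the bin b with cumulative BED in (b - width, b].

    Returns None for fractions beyond the last bin's upper edge (dropped from
    analysis).
    """
    bed = cumulative_bed(schedule, k)
    width = bins[1] - bins[0] if len(bins) > 1 else bins[0]
    for b in bins:
        if b - width < bed <= b:
            return b
    return None


def bin_drfs(
    per_fraction_features: pd.DataFrame,
    schedule: Schedule,
    bins: tuple[float, ...] = DEFAULT_BINS,
    include_first_fraction: bool = True,
) -> pd.DataFrame:
    """Average per-fraction DRFs into BED bins for one patient.

    Parameters
    ----------
    per_fraction_features:
        Wide frame indexed by fraction number (1..n) with one column per
        feature name.
    include_first_fraction:
        Whether fraction 1 (DRF identically 0) participates in its bin's mean.

    Returns
    -------
    Wide frame indexed by bin upper edge; NaN marks missing bins (beyond the
    schedule) and features dropped for a near-zero first-fraction baseline.
    """
    if 1 not in per_fraction_features.index:
        raise ValueError("features for fraction 1 are required as the DRF baseline")
    rf1 = per_fraction_features.loc[1]
    flagged = rf1.abs() < RF1_EPS

    rows = {}
    for k in per_fraction_features.index:
        if k == 1 and not include_first_fraction:
            continue
        b = assign_bin(schedule, int(k), bins)
        if b is None:
            continue
        drf = (per_fraction_features.loc[k] - rf1) / rf1.abs().clip(lower=RF1_EPS)
        rows.setdefault(b, []).append(drf)
    if not rows:
        raise ValueError("schedule too short: no fraction falls in any BED bin")

    out = pd.DataFrame(
        {b: pd.concat(v, axis=1).mean(axis=1) for b, v in rows.items()}
    ).T.reindex(list(bins))
    out.index.name = "bin"
    out.loc[:, flagged[flagged].index] = np.nan
    return out
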