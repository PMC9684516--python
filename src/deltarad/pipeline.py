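"""End-to-end pipeline: simulate -> preprocess -> extract -> delta/bin ->
label -> model, with every intermediate persisted as CSV/JSON.

Reruns with the same configuration are byte-identical; every output directory
carries the configuration hash in its manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import endpoints as ep
from . import features as ft
from . import longitudinal as lg
from . import modeling as md
from . import preprocessing as pp
from .exceptions import ConfigurationError, DeltaRadError
from .imaging import resample_isotropic
from .synthetic_cohort import CohortConfig, SyntheticPatient, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline", "extract_cohort_features", "compute_drf_matrix",
           "compute_labels", "run_models"]

ENDPOINTS = ("acute_gu", "subacute_gu", "delta_ipss")
IPSS_BASELINE = "IPSS Baseline"


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    quantizer: str = "uniform"
    collewet: bool = False
    n_levels: int = 256
    fiducial_radius_mm: float = 5.0
    resample_mm: float | None = 1.0
    bins: tuple[float, ...] = lg.DEFAULT_BINS
    endpoints: tuple[str, ...] = ENDPOINTS
    model_seed: int = 0
    n_bootstrap: int = 1000
    max_features: int = md.MAX_SELECTED
    cv_mode: str = "bootstrap_loo"
    output_dir: str = "deltarad_run"
    save_volumes: bool = False
    volume_format: str = "nrrd"

    def __post_init__(self) -> None:
        if self.quantizer not in ("uniform", "lloyd_max"):
            raise ConfigurationError(f"unknown quantizer {self.quantizer!r}")
        for e in self.endpoints:
            if e not in ENDPOINTS:
                raise ConfigurationError(f"unknown endpoint {e!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = {
                k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v
                for k, v in cohort.items()
            }
            for key in ("schedules",):
                if key in cohort and not isinstance(cohort[key], tuple):
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**cohort)
        for key in ("bins", "endpoints"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "grid_shape" in d:
            raise ConfigurationError("grid_shape belongs under 'cohort'")
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # hash identifies the analysis, not its location
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _preprocess_fraction(config: RunConfig, fraction) -> tuple:
    """resample -> fiducial artifact removal -> optional re-segmentation ->
    quantization, returning (volume, final mask, quantized ROI)."""
    vol, mask = fraction.volume, fraction.mask
    if config.resample_mm:
        vol, mask = resample_isotropic(vol, mask, config.resample_mm)
    result = pp.remove_fiducial_artifacts(
        vol, mask, list(fraction.fiducial_centers_mm), radius_mm=config.fiducial_radius_mm
    )
    mask = result.cleaned_mask
    if config.collewet:
        mask = pp.collewet_resegment(vol, mask)
    quantize = pp.quantize_lloyd_max if config.quantizer == "lloyd_max" else pp.quantize_uniform
    q = quantize(vol, mask, n_levels=config.n_levels, collewet_applied=config.collewet)
    return vol, mask, q


def _fractions_needed(patient: SyntheticPatient, bins) -> list[int]:
    """Fractions to extract: baseline plus every fraction mapping to a bin."""
    ks = [1]
    for k in range(2, patient.schedule.n_fractions + 1):
        if lg.assign_bin(patient.schedule, k, bins) is not None:
            ks.append(k)
    return ks


def extract_cohort_features(
    config: RunConfig, patients: list[SyntheticPatient]
) -> pd.DataFrame:
    """Per-fraction feature table, tidy: patient_id, fraction, feature, value.

    Only fractions that participate in some BED bin (plus the baseline
    fraction) are extracted.
    """
    rows = []
    for pt in patients:
        for k in _fractions_needed(pt, config.bins):
            try:
                vol, mask, q = _preprocess_fraction(config, pt.get_fraction(k))
                fv = ft.extract_features(vol, mask, q)
            except DeltaRadError as exc:
                raise DeltaRadError(
                    f"feature extraction failed at patient {pt.patient_id}, fraction {k}: {exc}"
                ) from exc
            for name, value in fv.items():
                rows.append((pt.patient_id, k, name, value))
    return pd.DataFrame(rows, columns=["patient_id", "fraction", "feature", "value"])


def compute_drf_matrix(
    config: RunConfig, patients: list[SyntheticPatient], features_long: pd.DataFrame
) -> pd.DataFrame:
    """Long DRF matrix: patient_id, bin, feature, value (NaN-free rows only)."""
    schedules = {pt.patient_id: pt.schedule for pt in patients}
    out = []
    for pid, grp in features_long.groupby("patient_id", sort=True):
        wide = grp.pivot(index="fraction", columns="feature", values="value")
        binned = lg.bin_drfs(wide, schedules[pid], bins=config.bins)
        long = binned.stack(future_stack=True).reset_index()
        long.columns = ["bin", "feature", "value"]
        long.insert(0, "patient_id", pid)
        out.append(long.dropna(subset=["value"]))
    return pd.concat(out, ignore_index=True)


def compute_labels(
    config: RunConfig, patients: list[SyntheticPatient]
) -> pd.DataFrame:
    """Binary endpoint labels per (patient, endpoint, bin)."""
    rows = []
    for pt in patients:
        for b in config.bins:
            rows.append(
                (pt.patient_id, "acute_gu", b, ep.label_acute_gu(pt.toxicity_events, b))
            )
            rows.append(
                (pt.patient_id, "subacute_gu", b, ep.label_subacute_gu(pt.toxicity_events))
            )
            _, cat = ep.label_delta_ipss(pt.ipss_initial, pt.ipss_final)
            rows.append((pt.patient_id, "delta_ipss", b, cat))
    return pd.DataFrame(rows, columns=["patient_id", "endpoint", "bin", "category"])


def _design_matrices(
    config: RunConfig,
    patients: list[SyntheticPatient],
    drf_long: pd.DataFrame,
    labels: pd.DataFrame,
    endpoint: str,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series, pd.Series]:
    """Pooled design matrix (rows = patient x bin), labels, and row keys."""
    wide = drf_long.pivot_table(
        index=["patient_id", "bin"], columns="feature", values="value"
    )
    wide = wide.dropna(axis=1)  # features flagged for any patient are dropped cohort-wide
    if endpoint == "delta_ipss":
        ipss = {pt.patient_id: pt.ipss_initial for pt in patients}
        wide[IPSS_BASELINE] = [ipss[pid] for pid, _ in wide.index]
    lab = labels[labels.endpoint == endpoint].set_index(["patient_id", "bin"])["category"]
    y = lab.loc[wide.index].to_numpy()
    pids = pd.Series([i[0] for i in wide.index], index=wide.index)
    bins_col = pd.Series([i[1] for i in wide.index], index=wide.index)
    return wide, y, pids, bins_col


def run_models(
    config: RunConfig,
    patients: list[SyntheticPatient],
    drf_long: pd.DataFrame,
    labels: pd.DataFrame,
) -> dict[str, dict]:
    """Feature selection (pooled across bins) and per-bin model fits for each
    configured endpoint.  Returns {endpoint: report dict}."""
    reports: dict[str, dict] = {}
    for endpoint in config.endpoints:
        X, y, pids, bins_col = _design_matrices(config, patients, drf_long, labels, endpoint)
        if np.unique(y).size < 2:
            reports[endpoint] = {"endpoint": endpoint, "unevaluable": True, "models": []}
            continue
        exempt = (IPSS_BASELINE,) if endpoint == "delta_ipss" else ()
        ranking = md.rf_gini_importance(X, y, seed=config.model_seed)
        filtered = md.correlation_filter(X, ranking, exempt=exempt)
        selected = md.select_features(filtered, max_k=config.max_features)
        models = []
        for b in config.bins:
            in_bin = bins_col == b
            if not in_bin.any():
                continue
            res = md.build_bin_model(
                endpoint,
                b,
                X.loc[in_bin.values],
                y[in_bin.values],
                selected,
                n_iter=config.n_bootstrap,
                seed=config.model_seed + int(b),
                mode=config.cv_mode,
            )
            models.append(res)
        reports[endpoint] = {
            "endpoint": endpoint,
            "selected_features": selected,
            "ranking": [[n, v] for n, v in ranking],
            "models": [m.to_dict() for m in models],
            "auc_distributions": {
                str(m.bin): [float(a) for a in m.auc_distribution] for m in models
            },
        }
    return reports


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and persist all artifacts under ``config.output_dir``.

    Returns the run manifest (also written as ``manifest.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    _write_json(out / "config.json", config.to_dict())

    patients = generate_cohort(config.cohort)
    if config.save_volumes:
        write_cohort(patients, out / "cohort", volume_format=config.volume_format)

    features_long = extract_cohort_features(config, patients)
    features_long.to_csv(out / "features.csv", index=False)

    drf_long = compute_drf_matrix(config, patients, features_long)
    drf_long.to_csv(out / "drf.csv", index=False)

    labels = compute_labels(config, patients)
    labels.to_csv(out / "labels.csv", index=False)

    reports = run_models(config, patients, drf_long, labels)
    auc_rows = []
    for endpoint, rep in reports.items():
        _write_json(out / f"model_{endpoint}.json", rep)
        for b, dist in rep.get("auc_distributions", {}).items():
            for it, a in enumerate(dist):
                auc_rows.append((endpoint, float(b), it, a))
    pd.DataFrame(auc_rows, columns=["endpoint", "bin", "iteration", "auc"]).to_csv(
        out / "auc_bootstrap.csv", index=False
    )

    manifest = {
        "config_hash": chash,
        "outputs": {},
    }
    skip = {"manifest.json", "config.json"}  # config.json embeds output_dir
    for name in sorted(p.name for p in out.glob("*.csv")) + sorted(
        p.name for p in out.glob("*.json") if p.name not in skip
    ):
        manifest["outputs"][name] = hashlib.sha256((out / name).read_bytes()).hexdigest()
    _write_json(out / "manifest.json", manifest)
    return manifest
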