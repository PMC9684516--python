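# deltarad

Delta-radiomics analysis of fractionated 3D image series: from per-fraction
volumes and ROI masks, through artifact removal, gray-level quantization and
3D texture feature extraction, to biologically-effective-dose (BED) binned
delta features and bootstrap-validated logistic models of binary toxicity
endpoints. A seeded phantom-cohort generator makes every stage testable
without any external data.

## Pipeline

1. **synthetic_cohort** — phantom cohorts: ellipsoidal ROIs filled with
   band-limited speckle whose contrast/correlation length drift with fraction
   index; implanted fiducials as bright rods with streak spokes; schedules,
   CTCAE-style toxicity events and IPSS scores with configurable
   outcome association (`texture_effect_size`).
2. **imaging** — `ImageVolume` / `ROIMask` containers, NRRD and NIfTI-1 I/O,
   isotropic resampling (trilinear image / nearest-neighbour mask, default
   1 mm).
3. **preprocessing** — fiducial streak-artifact removal (5 mm circle +
   spoke lines against a 3-sigma threshold from clean layers), 3-sigma
   re-segmentation (Collewet), uniform and Lloyd-Max quantization (default
   256 levels).
4. **features** — 42 base radiomic features (Global 3, GLCM 8, GLRLM 13,
   GLSZM 13, NGTDM 5), six volume-normalized variants and ROI volume
   (49 names). GLCM/GLRLM merge 13 directions before normalization; GLSZM
   zones and NGTDM neighbourhoods are 26-connected and mask-aware.
5. **longitudinal** — delta features `(RF_N - RF_1)/|RF_1|`, BED arithmetic
   `n·d·(1 + d/(α/β))` with α/β = 3 Gy, and averaging into 20-Gy BED bins
   (20–120 Gy).
6. **endpoints** — binary labels: acute GU toxicity (grade ≥ 2 after the bin's
   BED), sub-acute GU toxicity (grade ≥ 2 after treatment), and IPSS change
   (category 1 = improvement).
7. **modeling** — random-forest Gini ranking (500 trees, 2/3 bag, 7 features
   per split) on the pooled all-bins matrix, greedy |r| ≤ 0.8 correlation
   filtering, at most 7 selected features, per-bin logistic regression and
   leave-one-out AUC inside 1000 patient-level bootstrap resamples
   (median + 2.5/97.5 percentile CI).
8. **pipeline / cli** — configured, hashed, reproducible end-to-end runs.

## CLI

```sh
# write a synthetic cohort (volumes, masks, fiducials.csv, manifest.json)
deltarad simulate --config cohort.yaml --out cohort_dir --seed 7

# full run: simulate -> extract -> bin -> label -> model
deltarad run --config run.yaml --out run_dir

# feature extraction + DRF binning only
deltarad extract --quantizer lloyd_max --collewet 1 --out extract_dir

# model selected endpoints with preprocessing overrides
deltarad model --endpoint acute_gu --quantizer uniform --collewet 0 --seed 3
```

The YAML config mirrors `deltarad.pipeline.RunConfig` (with the cohort
parameters nested under `cohort:`). Outputs are tidy CSV tables
(`features.csv`, `drf.csv`, `labels.csv`, `auc_bootstrap.csv`), one JSON
model report per endpoint, and a `manifest.json` carrying the configuration
hash and SHA-256 of every artifact; re-running the same configuration
reproduces the artifacts byte-identically.

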