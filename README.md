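# morphoscreen

Triage of cytotoxic and nuisance compounds from cell-morphology feature
profiles, as a tested, reusable pipeline:

- **`morphoscreen.io`** — well-level profile tables (CSV with reserved
  metadata columns + feature columns), plate-map validation, and feature-space
  alignment between datasets.
- **`morphoscreen.normalize`** — field-to-well aggregation, per-plate robust
  z-scoring against vehicle (DMSO) wells (`(x − median) / (1.4826·MAD)`), and
  greedy correlation-based redundant-feature removal.
- **`morphoscreen.activity`** — Mahalanobis-distance activity scores per
  compound × concentration: PCA (scaled, uncentered) on stacked
  treatment + vehicle wells keeping components explaining ≥ 90% variance,
  sample-size-weighted pooled covariance, and an activity cutoff at
  mean + 3·SD of vehicle pseudo-group null distances. Relative cell number
  as % of same-plate vehicle mean.
- **`morphoscreen.cluster`** — hierarchical phenotype clustering with
  `1 − Pearson r` distances and Ward linkage, per-cluster mean signatures,
  correlation matching of external profiles to signatures (HC/NC calls),
  uncentered scaled PCA embedding, dendrogram entanglement, dot-plot style
  category summaries, and per-compound concentration trajectories.
- **`morphoscreen.health`** — live-cell time-course background correction
  (reagent-free wells) and trapezoid AUC summaries; glutathione
  quantification from luminescence plates via a 10-point standard curve
  (GSH = total − 2·GSSG, ratio withheld on outlier/negative-GSH flags).
- **`morphoscreen.synth`** — seeded synthetic 384-well screens (116 vehicle
  wells/plate, 4 positive controls, six 2-fold doses 0.625–20 µM across
  replicate plates), with planted phenotype signatures, block-correlated
  features, dose-dependent effects coupled to cell-count loss, 60-h time
  courses, and glutathione plates — plus ground truth for recovery tests.
- **`morphoscreen.evaluate`** — end-to-end recovery/calibration metrics on
  synthetic screens (used by the acceptance suite and report).

## CLI

```bash
morphoscreen --config config.yaml --outdir run/ all
# or stage by stage:
morphoscreen --config config.yaml --outdir run/ simulate
morphoscreen --config config.yaml --outdir run/ normalize
morphoscreen --config config.yaml --outdir run/ score
morphoscreen --config config.yaml --outdir run/ cluster
morphoscreen --config config.yaml --outdir run/ match
morphoscreen --config config.yaml --outdir run/ health
morphoscreen --config config.yaml --outdir run/ report
```

Example config (all keys optional; unknown keys are rejected):

```yaml
seed: 7
simulate:            # SynthConfig fields
  n_features: 120
  n_clusters: 9
  n_compounds_per_cluster: 2
normalize: {redundancy_threshold: 0.9, min_vehicle_wells: 8}
activity:  {variance_target: 0.90, sd_multiplier: 3.0}
cluster:   {k: 9}
match:     {hc_threshold: 0.5, nc_threshold: 0.2}
```

Each stage writes its tables plus a `manifest_<stage>.json` (parameters,
input hashes, seed, version). Reruns with identical config and seed are
byte-identical.

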