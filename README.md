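# kelpshift

Analysis pipeline for detecting and explaining thermal restructuring of
benthic macroalgae communities between two survey timepoints, paired with
extreme-event and trend analysis of a daily coastal SST record.

The package covers:

- **Survey data model** — paired 2 x 5 m quadrats, modified Braun-Blanquet
  cover codes converted to bin midpoints (`5` → 0.88, …, `+` → 0.005),
  sand-only quadrat exclusion, and a rare-species cover filter (default
  5 % in at least one quadrat).
- **Thermal affinity** — species temperature indices (STI) as the mean of
  a 0.1°-latitude-binned coastal SST climatology over each species'
  range; warm/cold classification against the historical community mean;
  abundance-weighted community temperature index (CTI) per quadrat.
- **CTI change** — mean paired CTI shift with a bootstrap CI (optional
  year-stratified depth-spline model), and a four-process decomposition
  (tropicalization, detropicalization, borealization, deborealization)
  computed in 1-m depth bins to correct for shallow-biased historical
  sampling.
- **Community statistics** — Bray-Curtis dissimilarity, one-way PERMANOVA
  (exhaustive enumeration when feasible, otherwise Monte-Carlo with the
  +1 correction), homogeneity of multivariate dispersion via principal
  coordinates, and SIMPER — all implemented from first principles and
  cross-checked against independent oracles in the test suite.
- **SST events and trends** — stress (≥ 14 consecutive days at ≥ 18 °C)
  and mortality (≥ 7 days at ≥ 20 °C) event detection, annual
  threshold-day counts, Mann-Kendall / Sen's slope, logistic
  event-frequency trends, GCV-spline warming rates (°C/decade), and
  baseline anomalies with Pearson correlation.
- **Synthetic data** — generators for every input with embedded ground
  truth (closed-form STIs, known CTI shifts, known process mixes,
  injected heat events, known warming trends), used for parameter
  recovery throughout the tests.

## CLI

The `kelpshift` console script exposes the stages
`simulate | sti | cti | shift | decompose | community | events | trends |
report` (where `report` runs the full analysis chain).  Every stage takes
a YAML config and an output directory:

```sh
kelpshift simulate --config config.yaml --out run/
kelpshift report   --config config.yaml --out run/ --json
```

A minimal config (all analysis defaults — thresholds, bin widths,
999 permutations, 2000 bootstrap resamples — are built in; the seed is
mandatory):

```yaml
seed: 42
paths:
  surveys: run/surveys.csv
  species: run/species.csv
  climatology: run/climatology.csv
  daily_sst: run/daily_sst.csv
simulate:
  community: {n_quadrats: 48, target_delta_cti: 1.4, delta_cti_sd: 0.5}
  sst: {trend_per_decade: 0.33, noise_sd: 0.3}
```

File layouts (all plain CSV/JSON): long-format surveys
(`quadrat_id, transect_id, year, depth_m, substrate, species,
cover_code|cover_fraction`), species metadata
(`name, functional_group, lat_min, lat_max`), climatology
(`lat_center, mean_sst`), daily series (`date, sst_c[, psu]`).

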