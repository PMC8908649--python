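# wmhnet

Graph-theoretical analysis of resting-state functional brain networks in
cohorts stratified by white-matter-hyperintensity (WMH) severity.

The pipeline goes from per-region BOLD time series to group statistics:

1. **`wmhnet.cohort`** — seeded synthetic cohorts: two severity groups
   defined by summed Fazekas lesion grades (totals 1–2 vs 3–6), regional
   time series drawn from a modular block covariance whose within-module
   coupling is attenuated in the high-severity group, lognormal lesion
   volumes, demographics, and MoCA/MMSE scores optionally coupled to a
   designated node's connectivity strength.
2. **`wmhnet.preprocess`** — temporal cleaning: discard initial volumes,
   linear detrend, zero-phase 0.01–0.08 Hz Butterworth band-pass, OLS
   nuisance regression.
3. **`wmhnet.connectivity`** — Pearson correlation matrices, Fisher
   z-transform, fixed-density (sparsity) thresholding into binary networks
   across a grid of 0.05–0.40, plus |z|-weighted networks.
4. **`wmhnet.metrics`** — clustering coefficient, characteristic path
   length, global/local/nodal efficiency on binary and weighted graphs;
   small-world ratios γ, λ, σ against Maslov–Sneppen degree-preserving
   rewired null ensembles; per-threshold profiles with an
   across-threshold arithmetic-mean summary.
5. **`wmhnet.inference`** — Shapiro–Wilk-gated Welch t / Mann–Whitney U
   group comparisons with Benjamini–Hochberg FDR (global and nodal
   families corrected separately), chi-square tests, logistic age
   adjustment, partial correlation with age/sex/education covariates,
   Cohen's κ and Cronbach's α rater reliability.
6. **`wmhnet.pipeline` / `wmhnet.cli`** — config-driven orchestration with
   byte-reproducible outputs.

## CLI

```sh
wmhnet run-all --config config.yaml --seed 7 --out runs/demo
```

Subcommands `simulate`, `preprocess`, `connect`, `metrics`, `stats` run
prefixes of the pipeline; `run-all` runs every stage enabled in the
config. A minimal config:

```yaml
cohort:
  n_group_a: 16
  n_group_b: 16
  n_regions: 90
  n_timepoints: 200
  group_b_attenuation: 0.4
sparsity_grid: [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4]
null_ensemble: {n_random: 100, swaps_per_edge: 10, seed: 0}
seed: 7
out_dir: runs/demo
```

Outputs land under `out_dir`: the written cohort, per-subject Fisher-z
matrices, per-subject global/nodal metric profiles, and the statistics
tables (`global_comparisons.csv`, `nodal_comparisons.csv`,
`volume_correlations.csv`, `cognition_correlations.csv`), plus the
serialized config and a run log. Re-running with the same config and seed
reproduces every table byte-identically.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed forms,
oracle equivalences against brute-force references, sparsity exactness,
stochastic null calibration, effect-direction recovery, small-world
sanity, end-to-end determinism). One acceptance assertion is a known,
deliberate failure: under fixed-density rank thresholding, attenuating
block coupling cannot lower group B's global efficiency (random edge
placement maximizes efficiency at fixed density), so the published Eglob
direction is unreachable for this generative family; the test documents
rather than hides this.

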