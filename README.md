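# pbsi

Person-based similarity index (PBSI) analysis of regional brain morphometry
profiles, as a tested, reproducible pipeline.

For each subject, the PBSI is the average Spearman correlation between their
ordered vector of regional measures — cortical thickness (CT) or subcortical
volume (SV), treated as separate phenotypes — and the corresponding vectors
of every other subject in the same diagnostic group, site, and modality
(`n − 1` coefficients averaged per subject). Because the index is
rank-based, it captures relative inter-regional patterns and is independent
of global scale. Elevated within-group heterogeneity of brain structure
lowers within-group PBSI.

The package provides:

- **`pbsi.cohort`** — synthetic multi-site, multi-group cohort generation
  with a shared inter-regional template, additive age/sex effects, and a
  per-group dispersion (heterogeneity) knob, so the whole pipeline is
  testable without external data.
- **`pbsi.io`** — reading/validating/writing morphometry tables (CSV/TSV,
  `ct__`/`sv__` column prefixes or an explicit YAML region schema; default
  schema: 64 CT + 18 SV bilateral Desikan-style labels).
- **`pbsi.core`** — the index itself plus regional diagnostics:
  leave-one-out contributions (mean |ΔPBSI| per region) and bootstrap
  subset resampling (random region subsets on a size grid, e.g.
  10…60 step 10 × 100 reps for CT, half the regions for SV).
- **`pbsi.stats`** — Mann–Whitney U with tie-corrected Z (exact enumeration
  for small tie-free inputs), Cliff's delta, Feltz–Miller asymptotic test
  for equality of coefficients of variation, KS normality screen, Spearman
  associations, Benjamini–Hochberg FDR, and Tukey-fence outlier handling.
- **`pbsi.pipeline`** — config-driven end-to-end runs with byte-for-byte
  reproducibility given (config, seed).

## CLI

```sh
# generate a synthetic cohort (YAML spec with CohortSpec fields)
pbsi simulate --spec spec.yaml --out simdir/

# per-subject PBSI within each (group, site, modality) cell
pbsi compute --table simdir/cohort.csv --out scores.csv
pbsi compute --table cohort.csv --pool-groups bd,scz --out pooled.csv

# regional diagnostics
pbsi contributions --table simdir/cohort.csv --out contrib/ \
    --subsets 10:60:10 --reps 100 --seed 1 --modality CT

# group contrasts (Mann-Whitney + Cliff's delta, FDR per contrast family)
pbsi compare --pbsi scores.csv --contrast hc:scz --out contrasts.csv

# the full battery from one config file
pbsi run --config run.yaml
```

A minimal `run.yaml`:

```yaml
cohort:
  n_per_group: 40
  groups: [hc, scz]
  sites: [siteA]
  n_ct_regions: 64
  n_sv_regions: 18
  within_group_dispersion: {hc: 0.2, scz: 0.8}
contrasts:
  - {a: hc, b: scz}
subset_reps: 100
seed: 7
outdir: out/
```

Outputs are tidy CSVs (`pbsi.csv`, `boxplots.csv`, `contributions_loo.csv`,
`subset_stability.csv`, `cv.csv`, `comparisons.csv`, `associations.csv`)
plus `summary.md` and `provenance.json`. Exit codes: 0 success,
2 configuration error, 3 data error, 1 internal error.

Sign conventions: negative Z / negative Cliff's d mean the first-listed
group is stochastically smaller. Outlier trimming uses Tukey fences at
1.5×IQR per cell; trimmed and untrimmed statistics are both reported.

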