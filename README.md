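# alcomediome

Analysis toolkit for studying how alcohol intake relates to the gut
microbiome and advanced colorectal lesions in screening cohorts. The
package covers the full analysis chain:

- **`alcomediome.exposure`** — alcohol-exposure derivation (g/day
  categories with right-open 10/20 g boundaries, sex-specific guideline
  adherence, alcohol units at 12 g, ethanol energy percentage at 7 kcal/g),
  sex-specific energy-intake exclusions, and covariate codings (moderate +
  2× vigorous activity, ten-year smoking/snus quit rule, BMI, median
  imputation and explicit "missing" category levels).
- **`alcomediome.association`** — baseline-logit multinomial logistic
  regression (Newton iteration with analytic gradient/observed information,
  ridge fallback, Wald CIs), odds-ratio tables for categorical, per-10 g,
  per-twofold, adherence and consumer codings, ordinal trend tests and Wald
  interaction tests.
- **`alcomediome.diversity`** — Shannon / inverse Simpson indices,
  percent-difference regressions on log indices, Bray–Curtis distances,
  principal coordinates, covariate-adjusted PERMANOVA (marginal sums of
  squares, Freedman–Lane residual permutation, partial omega-squared) and
  group-dispersion comparisons.
- **`alcomediome.diffabund`** — prevalence filtering (inclusive 0.1
  default), optional total-sum scaling, log2 transform with pseudo-counts,
  vectorized per-feature covariate-adjusted linear models,
  Benjamini–Hochberg correction, mutual-adjustment refits.
- **`alcomediome.score`** — cross-validated log-ratio microbial score
  (log of summed "elevated" over summed "depleted" taxon abundances with a
  shared pseudo-count); taxa selected by differential abundance within
  seeded, outcome-stratified folds so no sample is scored with taxa chosen
  from its own data.
- **`alcomediome.mediation`** — counterfactual mediation decomposition on
  the risk-difference scale (ACME, ADE, total effect, proportion mediated)
  for twofold alcohol increases, with nonparametric percentile bootstrap
  CIs.
- **`alcomediome.synth`** — synthetic cohort/microbiome generator with a
  known mediation ground truth (numerically integrated true ACME/ADE) used
  throughout the test suite for parameter-recovery checks.

## Command-line usage

The `alcomediome` console script chains the stages over plain-text tables
(TSV metadata with `participant_id` first; abundance tables in merged
profiler layout, features × samples):

```bash
alcomediome synth    --config cfg.yaml --out data/
alcomediome exposure --meta data/meta.tsv --out data/meta_derived.tsv --log data/exclusions.json
alcomediome assoc    --meta data/meta_derived.tsv --coding per_twofold --out assoc.tsv
alcomediome diversity --abund data/species.tsv --meta data/meta_derived.tsv \
                      --term adherence --nperm 999 --seed 42 --out alpha.tsv
alcomediome diffabund --abund data/species.tsv --meta data/meta_derived.tsv \
                      --exposure twofold --normalization none --out da.tsv
alcomediome score    --abund data/species.tsv --meta data/meta_derived.tsv \
                      --k 5 --seed 42 --out score.tsv
alcomediome mediate  --meta data/meta_derived.tsv --score score.tsv \
                      --nboot 1000 --seed 42 --out mediation.json
```

`cfg.yaml` holds `alcomediome.synth.SynthConfig` fields, e.g.
`n_participants: 1000`.

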