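# hybridkit

Marker-assisted hybrid identification and quantitative-trait evaluation for
cross-pollinated grass breeding programs.

The toolkit covers the full desk-side workflow of an F1/BC1 hybrid breeding
cycle built on dominant (presence/absence) SSR band scores:

- **`hybridkit.simdata`** — synthetic diploid parents, F1/BC1 offspring band
  matrices with a known maternal-selfing contamination rate, and correlated
  12-trait tables, so every downstream stage is testable without external
  data.
- **`hybridkit.markers`** — band-matrix CSV I/O, characteristic-band
  detection (bands present in exactly one parent), true-hybrid/maternal-type
  classification and population purity, dominant-marker diversity statistics
  (observed/effective allele number, gene diversity, Shannon index, %
  polymorphic bands), and genetic-similarity matrices (simple matching,
  Dice, Jaccard).
- **`hybridkit.quantgen`** — KS normality screening (plug-in or Lilliefors),
  moment skewness/kurtosis, CV, pairwise Pearson correlation with 0.1 / 0.05
  / 0.01 significance tiers, mid-parent heterosis and heterobeltiosis,
  spike self-fertility summaries with a Welch test, the false-hybrid-vs-
  selfing-rate cross-check, and cross-combination survival summaries.
- **`hybridkit.scoring`** — PCA of the standardized traits (correlation
  matrix), contribution rates, per-plant component scores and the
  contribution-weighted synthesis score `Z` used to rank and select
  backcross-parent candidates (`Z > 0.80` by default).

## CLI

```sh
# write a deterministic synthetic fixture set
hybridkit simulate --scenario paper-like-F1 --seed 42 --out fixtures/

# characteristic bands, hybrid calls, purity, diversity, similarity
hybridkit identify --band-matrix fixtures/band_matrix.csv \
    --mother-id MOTHER --father-id FATHER --out identify/

# normality, correlation, heterosis, PCA scores + Markdown report
hybridkit evaluate --traits fixtures/traits.csv \
    --parent-means fixtures/parent_means.csv --out evaluate/

# consolidate both stages into a single report
hybridkit report --identify-dir identify/ --evaluate-dir evaluate/ \
    --out report.md
```

Every run writes a `resolved_config.json` snapshot; options may also come
from a YAML config file (`--config`), with command-line flags taking
precedence. Exit codes: 0 success, 1 data/validation error, 2 usage error.

### Band matrix dialect

CSV with first column `individual_id`; remaining columns are named
`primer__locus` (double underscore); cells are `0`, `1` or `NA`. The mother
and father rows are designated by id via flags.

## Notes and caveats

- **Purity convention.** Purity = 100 × (tested − maternal-type) / tested,
  with unresolved plants (all paternal characteristic calls missing)
  excluded from the denominator. One published BC1 line prints the formula
  with the true-hybrid count in the subtrahend position; this implementation
  always subtracts the maternal-type count, which matches the stated result
  (137/143 = 95.80%).
- **Heterosis from rounded means.** Heterosis recomputed from rounded
  published means reproduces the reference values for reproductive tiller
  number, nutritional tiller number (HB), tiller height and spikelet number
  per spike; cells for e.g. thousand kernel weight and seed number per plant
  were evidently computed from unrounded data and do not recompute from the
  printed means — they are excluded from acceptance checks.
- **PCA signs.** Eigenvector signs are oriented so the largest-|loading|
  entry is positive. `Z` is not sign-invariant, so per-plant scores from a
  refit match published tables only up to component sign; recomputing a
  published `Z` from printed component scores uses
  `scoring.synthesis_score_from_weights` directly.
- **Similarity coefficient.** The default is simple matching; Dice and
  Jaccard are provided. No claim is made about which coefficient produced
  any specific published range.
- **Simulator limits.** Loci segregate independently (no linkage), selfing
  is the only contamination mode, and missingness is completely at random.
  Traits in `skew_traits` go through a standardized monotone exponential
  tilt after correlation is imposed, preserving mean and CV exactly and
  Pearson correlation only approximately (±0.1).
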