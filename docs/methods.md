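# Methods

## Scope

`seedfx` implements a complete desk-scale analysis of RNAi
morphological-profiling data: a generative model of an arrayed shRNA
Cell Painting experiment, the normalization/aggregation/PCA pipeline
that turns per-cell features into per-well and per-sequence profiles,
and the correlation-group analysis that compares replicate, same-gene
and same-seed profile similarity against an empirical null. Image
processing itself (segmentation, feature extraction, illumination
correction) is out of scope: per-cell feature tables arrive precomputed.

## Generative model

An experiment is a library of reagents, a plate layout set, and a
per-cell feature table.

**Library.** `n_genes × shrnas_per_gene` gene-targeting reagents plus
`n_controls` no-target controls, each a random 21-mer over ACGT. The
seed is the hexamer at sense positions 12–17 (anchor, start and length
are configurable; a guide-strand anchor reads the window off the
reverse complement). Exactly `n_seed_pairs` cross-gene pairs are forced
to share a seed hexamer; all other seeds in the library are distinct,
so seed sharing is exactly the engineered set. Library generation fails
explicitly when the requested number of distinct seeds exceeds 4^length
or the pairing is infeasible.

**Layouts.** Two well-position permutations of the library, each copied
onto `n_layout_replicates` plates, give `2 × n_layout_replicates`
replicate wells per reagent. Layout 2 is a derangement of layout 1, so
every reagent genuinely occupies two distinct positions. Untreated
wells sit at fixed positions shared by all plates; position effects are
carried by the well-noise term regardless, which is why the simpler
fixed design suffices.

**Effects.** Each reagent's latent phenotypic effect is

    t = g + s + e,    g ~ N(0, σ_g² I_d),  s ~ N(0, σ_s² I_d),  e ~ N(0, σ_q² I_d)

with `g` shared within a gene, `s` shared within a seed, and `e`
reagent-specific; controls have `g = 0`, untreated wells `t = 0`. A
fixed loading matrix `L` (F × d, unit-norm columns, drawn once from
`loading_seed`) maps latent effects to features. A cell in well w of
plate p measures

    x = μ_p + L t + w_pw + ε_cell.

**Noise structure.** μ_p, w_pw and ε_cell are Gaussian but *correlated
across features*: each is drawn in a `noise_rank`-dimensional subspace
and mapped through a second fixed matrix with unit-norm rows, so every
feature's marginal noise sd is exactly its configured σ while the noise
covariance has rank `noise_rank`. This is deliberate and load-bearing.
Real image-derived features are massively redundant — a 99%-variance
PCA of a Cell Painting well-profile matrix retains a few hundred
directions out of ~1400 features — so nuisance variation concentrates
in a few dominant axes (cell density, focus, staining intensity,
illumination, edge effects). White per-feature noise would instead add
an isotropic variance floor spanning all F dimensions; the 99% PCA cut
then retains hundreds of pure-noise components, and because Spearman's
ρ weights every retained coordinate equally (and trailing components
carry small negatively-correlated subspace-estimation residuals), rank
correlations between genuinely related profiles are driven toward zero.
No real profiling dataset shows such a floor, and no choice of effect
scales rescues the analysis under it.

## Defaults and units

All σ are standard deviations in normalized-feature units (after
median/MAD scaling an untreated cell's feature has sd ≈ 1).

| parameter | default | meaning |
|---|---|---|
| F (`n_features`) | 300 | features per cell |
| d (`latent_dim`) | 25 | dimension of the phenotype space |
| σ_g (`sigma_gene`) | 0.25 | on-target gene effect, per latent dim |
| σ_s (`sigma_seed`) | 1.0 | seed off-target effect, per latent dim |
| σ_q (`sigma_seq`) | 0.45 | sequence-specific residual, per latent dim |
| σ_w (`sigma_well`) | 0.15 | well effect, per-feature marginal sd |
| σ_p (`sigma_plate`) | 0.2 | plate baseline, per-feature marginal sd |
| σ_c (`sigma_cell`) | 1.0 | cell noise, per-feature marginal sd |
| `cells_per_well` | 60 | cells measured per well |
| `noise_rank` | 5 | rank of the correlated noise covariance |
| design | 20 genes × 5 shRNAs, 12 seed pairs, 4 controls | library |
| layouts | 2 × 2 plates, 384 wells, 8 untreated/plate | replication |

σ_s ≫ σ_g places the simulation in the seed-dominant regime the
analysis is designed to detect; the remaining scales keep a single
well's profile clearly above the noise while leaving the per-pair
correlations well away from 1, so group orderings are informative
rather than saturated. `noise_rank = 5` models nuisance variation
concentrated in a handful of dominant axes; it was set so that the
default experiment robustly exhibits the regime's qualitative
signatures across seeds (replicate reproducibility above 90%, same-seed
concordance above 70%, same-gene concordance near the null) rather than
straddling them. Raising it spreads nuisance variance over more
retained PCA components and dilutes all rank correlations. Gaussian
noise throughout is a knob, not a commitment: the analysis is
rank-based, so any monotone distributional change leaves results
essentially unchanged.

## Profiling pipeline

Order is fixed: normalize → feature mask → per-well median → PCA
fit/project → per-sequence median. Numerical conventions:

- Raw MAD (median of absolute deviations from the median) is stored
  per (plate, feature); the 1.4826 consistency factor is applied at
  division time. Features with zero MAD are left untouched by the
  normalizer and removed by the mask (retained iff MAD > 0 on *every*
  plate).
- After normalization, untreated cells on each plate have featurewise
  median exactly 0 and scaled MAD 1 (verified to numerical tolerance in
  the test suite).
- Medians of even counts are the midpoint of the two central order
  statistics; ties are kept as-is.
- PCA is standard mean-centered covariance PCA fit on all well profiles
  (treated and untreated) of the whole experiment — one shared profile
  space, not per-plate models. The retained count k is the smallest
  number of leading components with cumulative explained variance ≥ the
  threshold (default 0.99). No per-feature re-standardization is
  applied before PCA beyond the robust normalization.
- Sequence profiles are medians of replicate well profiles taken in PCA
  space (taking them in feature space before projection is available
  for sensitivity analysis, since either order is defensible).
- Degenerate inputs are dropped with logged warnings, never imputed:
  wells emptied by QC exclusions, sequences with no surviving wells,
  and correlation pairs involving a zero-rank-variance profile.

## Correlation analysis

Pair relations at the sequence level are mutually exclusive by
construction: same-gene pairs must differ in seed, same-seed pairs must
differ in gene, null pairs differ in both. The well-level null uses
well pairs of reagents satisfying the same constraints. This
"unrelated reagents" null is the only definition that can calibrate
both the well-level and the sequence-level analyses with one rule; the
choice is echoed in every run manifest. No-target controls are excluded
from all default groups and analyzed separately on request, with each
control construct label standing in as a gene.

Spearman's ρ is Pearson on average ranks; the bulk path rank-transforms
every profile once and reads all pairs off one correlation matrix,
which is algebraically identical to the pairwise definition (the test
suite proves equality against the 1 − 6Σd²/(n(n²−1)) closed form on all
pairs of length-5 permutations). The significance threshold is the
empirical 95th percentile of the null correlations, computed with
linear interpolation between order statistics (nearest-rank offered as
an option); "significant" means strictly above the threshold, so
negative correlations never count. Group means are compared with a
two-sided two-sample t-test; Welch's unequal-variance form is the
default for robustness, and the classic equal-variance statistic is
reported alongside it. p-values are raw: the analysis makes a handful
of group-level comparisons, not a multiple-testing screen.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the study design — two
layouts, replicated plates, untreated anchor wells, engineered
cross-gene seed pairs, controls — and the qualitative regime: highly
reproducible profiles whose between-reagent similarity is governed by
the seed, not the gene. Passing tests therefore demonstrate that the
pipeline and statistics faithfully implement the intended analysis and
can recover a known effect hierarchy.

They do not validate the magnitudes of real biology. The additive
latent model has no dose-response, no knockdown-efficiency variation,
no microRNA-pathway mechanism (the seed effect is a latent vector, not
a transcriptome model), no cell-cycle or density covariates, and
Gaussian margins. Scale is reduced for desk runtime: 300 features, 60
cells/well, 4 replicate wells per reagent, 100 reagents — roughly a
tenth of the real experiment in each direction, sizes chosen so the
full chain runs in seconds. One visible consequence: with 60 cells per
well, the per-well median carries a sampling residual that is a few
percent of total profile variance, so the 99%-variance PCA retains a
larger fraction of dimensions (~108 of 300) than a full-scale
experiment would (205 of 1301). Effect scales were set to reproduce the
qualitative ordering of the group statistics, not any exact printed
percentage.

## Known limitations

- The engineered same-seed group is small (12 pairs by default), so its
  significant fraction moves in 8.3-point steps; judgments about it are
  stable across seeds but individual runs are granular.
- The feature-subset analysis (e.g. nuclear-shape-only runs) re-fits
  PCA on the subset; comparisons across subsets therefore compare
  different spaces, as in the original analysis style.
- Per-plate normalization assumes every plate carries untreated wells
  with at least a handful of cells; plates without them fail loudly.
- With extremely low `noise_rank` (1–2) the null distribution acquires
  visible structure from shared noise axes; the default keeps the null
  threshold within a hair of its nominal calibration (the 5% check in
  the suite).
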