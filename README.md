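# seedfx

Morphological profiling measures thousands of image-derived features per
cell and condenses them into a multivariate *profile* per perturbation.
When the perturbations are RNAi reagents (e.g. lentiviral shRNAs), two
kinds of signal compete inside each profile: the intended **on-target**
effect of knocking down the target gene, and **off-target** repression
driven by the reagent's 6-nt *seed* sequence acting through the microRNA
pathway. `seedfx` is a toolkit for quantifying that competition: it
builds profiles from per-cell feature tables exactly as a Cell Painting
analysis would, scores profile similarity within biologically meaningful
pair groups against an empirical null, and ships a synthetic-data
generator with known gene/seed/sequence ground truth so every stage of
the analysis is testable at desk scale.

It is aimed at computational biologists working with image-based
profiling screens who need to (a) reproduce this style of analysis on
their own per-cell data, or (b) benchmark methods that claim to separate
on-target from seed-driven signal.

## The analysis

Starting from per-cell feature tables keyed by plate and well, plus
per-well treatment metadata:

1. **Robust per-plate normalization.** For each feature, the median *m*
   and median absolute deviation *a* are computed across all untreated
   cells of the plate; every cell value is transformed to
   `(x − m) / (1.4826 · a)`. The constant 1.4826 makes the scaled MAD a
   consistent estimator of σ under normality.
2. **Feature filtering.** Features with `a = 0` on any plate are
   excluded.
3. **Per-well profiles.** Featurewise median across the cells of the
   well (after any QC well exclusions).
4. **PCA.** Fit on all well profiles; the smallest number of leading
   components whose cumulative explained variance reaches 99% is
   retained, and profiles are projected into that space.
5. **Per-sequence profiles.** Featurewise median of each reagent's
   replicate well profiles, in PCA space.
6. **Correlation groups.** Spearman's ρ is computed for profile pairs in
   each relation — *replicate* (same reagent, different wells),
   *same-gene* (different reagents, same target, different seeds),
   *same-seed* (different reagents, identical seed, different targets) —
   and for *null* pairs sharing neither gene nor seed. The 95th
   percentile of the null distribution defines the significance
   threshold; each group is summarized by its fraction of significant
   correlations, and group means are compared by two-sided t-tests
   (Welch by default, classic Student also reported).

The synthetic generator draws each reagent's latent effect as
`t = g + s + e` (gene + seed + sequence-specific components), maps it to
feature space through a fixed loading matrix, and adds correlated plate,
well and cell-level Gaussian noise. With the default scales
(σ_seed = 1.0 ≫ σ_gene = 0.25) it reproduces the seed-dominant regime:
replicates are highly reproducible, same-seed pairs are strongly
concordant, same-gene pairs are barely above the null.

## Worked example

```python
from seedfx.io import RunConfig
from seedfx.pipeline import run_chain
from seedfx import report

bundle = run_chain(RunConfig.from_master_seed(1))
summary = report.write_summary(bundle["results"], "summary.csv")
print(summary.to_string(index=False))
```

prints

```
   level  relation     n  mean_rho  pct_significant  threshold  p_welch_vs_null  p_student_vs_null
    well replicate   600  0.373232        98.666667   0.169821         0.000000       0.000000e+00
    well null_pair 75808 -0.005166         5.000791   0.169821              NaN                NaN
sequence same_gene   200  0.007428         5.500000   0.169744         0.156312       1.400970e-01
sequence same_seed    12  0.223110        75.000000   0.169744         0.000005       1.650857e-13
sequence null_pair  4738 -0.003906         5.002111   0.169744              NaN                NaN
```

Reading the table: 98.7% of the 600 well-level replicate pairs correlate
above the null's 95th-percentile threshold — profiles are highly
reproducible. At the sequence level, 75% of the 12 engineered cross-gene
same-seed pairs are significantly correlated versus only 5.5% of the 200
same-gene pairs (not distinguishable from the 5% a calibrated null
yields by construction): the seed effect, not the on-target effect,
dominates the profiles. The t-tests confirm the same-seed group mean is
far above the null while the same-gene mean is not.

The same chain is available from the shell:

```bash
seedfx run-all --seed 1 --out results/
seedfx simulate --seed 1 --out sim/          # or stage by stage
seedfx profile --cells sim/cells.csv --metadata sim/metadata.csv --out prof/
seedfx analyze --sequence-profiles prof/sequence_profiles.csv \
    --well-profiles prof/well_profiles.csv --metadata sim/metadata.csv --out ana/
seedfx report --results ana/ --out figs/
```

Every run writes a JSON manifest (config echo, seeds) from which it can
be reproduced bit-identically.

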