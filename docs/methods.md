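# Methods

This note records the quantitative model behind `rejuvkit`, the reasoning
behind its defaults, and the numerical choices that affect results.

## Scientific setting

Transient reprogramming experiments express Yamanaka factors in somatic
cells for a limited window — through the maturation phase of iPSC
reprogramming, but stopping before cells commit to pluripotency — and then
withdraw them.  The central claim such experiments make is that treated
cells become *measurably younger* while *retaining their somatic identity*.
`rejuvkit` implements the measurement side of that claim: epigenetic and
transcriptomic age estimation, a site-level test for reversed aging
changes, an analysis of identity-gene dynamics and regulatory-element
methylation memory, and image-derived functional phenotypes.  Because the
original datasets behind such studies are large microarray and sequencing
cohorts, the package pairs every analysis with a seeded generator that
plants known ground truth at desk scale, so every estimator can be
validated by recovery rather than by reference to external data.

## Age transform

Chronological age is regressed on a piecewise scale

- F(a) = log2(a + 1) − log2(adult + 1) for a ≤ adult,
- F(a) = (a − adult) / (adult + 1) for a > adult,

with adult = 20 years by default.  The transform is continuous and strictly
increasing, with exact inverse (adult + 1)·2^t − 1 for t ≤ 0 and
t·(adult + 1) + adult for t > 0.  Round trips are exact to < 1e−9 over
[0, 120] years.  All clocks fit transformed age and report predictions in
years through the closed-form inverse.

## Methylation clocks

A clock is a linear predictor over CpG beta values (fractions in [0, 1]).
Training uses elastic-net regression (`l1_ratio` 0.5, alpha chosen by
5-fold cross-validation on a log-spaced grid 1e−4..1); the held-out error
reported is the *median* absolute error in years of back-transformed
predictions from an outer cross-validation.  Applying a clock handles
missing features by one of three policies — training-mean imputation
(default), fixed-value imputation, or dropping the feature's term — because
real arrays routinely lack a handful of clock sites.  Per-sample missing
counts are reported.

## Transcriptome clocks

Two variants are provided.

- `forest`: a random forest on log2 expression, with the `max_features`
  fraction chosen from {0.1, 0.3, 0.5, 0.7, 1.0} by 3-fold cross-validation.
- `binarized_linear`: expression is binarized per gene at its training-cohort
  median (strictly greater → 1, ties → 0) and an elastic net is fit on the
  binary matrix.  Binarization makes the clock robust to monotone
  distortions of expression scale across platforms.

Held-out error (`cv_mae`) is the median absolute error in years over a
repeated K-fold scheme (default 10 folds × 3 repeats).

A caveat that shaped the generator: if every gene changes *strictly
monotonically* with age, then thresholding each gene at its own median
produces features that all flip at the cohort's median age — the binary
matrix is degenerate and the clock cannot resolve age.  Binarized clocks
work in practice because many genes are switch-like: stable plateaus with a
relatively short transition whose timing varies across genes.  The
generator therefore models its nonlinear aging genes as such switches
(onsets uniform over 0–85 years, transitions of 5–15 years), which gives
binarized features informative, spread-out crossing ages.

## Aging trajectory

Genes correlated with age (Pearson; two-sided t-test p-values,
Bonferroni-corrected p·G ≤ α) are z-scored and decomposed by SVD; PC1 is
oriented so it increases with age, and an ordinary-least-squares fit of age
on PC1 converts projections to an age equivalent.  Query samples are
projected with the reference means/SDs, so cohort-level shifts (e.g.
treatment) appear as shifts along the reference axis.

## Rejuvenated CpGs and genes

A CpG qualifies as *aging-associated* if its fitted slope corresponds to at
least a 10% change in beta over 40 years (inclusive; tested with a 1e−12
epsilon so exact-boundary slopes qualify).  It is called *rejuvenated* if
the treated-minus-control mean beta difference opposes the sign of the
aging slope with magnitude above a configurable floor (default 0, i.e. any
opposing change).  Called sites are merged into regions (same chromosome,
gaps ≤ 1 kb, ≥ 2 sites) and annotated with the nearest TSS.  Gene-level
calls require a log2 aging effect of at least 0.5 per 40 years, an opposing
treatment shift, and a Benjamini–Hochberg-adjusted rank-sum p ≤ 0.05.
Set overlaps are tested with a one-sided Fisher exact test (hypergeometric
tail); the odds ratio uses a Haldane 0.5 correction only when a cell of the
2×2 table is zero.

## Identity memory

Fibroblast- and iPSC-specific gene sets are defined by differential
expression between the two states (Welch t-test by default, rank-sum as an
alternative; |log2 FC| ≥ 2 and BH-adjusted p ≤ 0.05).  Identity-gene
dynamics across reprogramming stages are summarized as per-gene stage-mean
trajectories, clustered by Ward agglomerative clustering into three
archetypes: `temporarily_down`, `temporarily_up` and `persistent`.
Trajectories are centred per gene but scaled by a single *global* factor
(the median per-gene SD): per-gene unit-variance scaling would amplify
flat trajectories into pure noise and destroy the flat-vs-changing
distinction that the archetypes encode.

Regulatory elements are linked to the nearest TSS within class-specific
windows — 1 kb for promoters, 1 Mb for enhancers — measured from the
element midpoint, ties broken deterministically by gene id.  Element
methylation is summarized as mean beta per element per sample group, and
"memory" is quantified by counting enhancers that are active in fibroblasts
but not in iPSCs and that gain ≥ 0.2 mean beta in a target state.  In the
simulated demo, enhancers that lose activity gain methylation in the
complete-reprogramming state but not in the transient arm, reproducing the
expected retention of somatic methylation.

## Image phenotypes

- *Roundness* is the maximum cell length divided by its perpendicular
  width, estimated by the major/minor axes of the moment-equivalent ellipse
  of the label footprint.  This estimator is rotation-invariant; pixel-corner
  caliper measurements were rejected because raster corners inflate diagonal
  lengths by up to √2 on near-round cells.  Accuracy is resolution-limited:
  at 4 pixels per micron a 40 × 10 µm ellipse measures 4.03 and a circle
  exactly 1.0.
- *Wound edge* detection scans columns (wound on the right) and takes the
  right-most column whose cell coverage reaches 0.5; *migration speed* is
  the least-squares slope of distance closed versus time in hours.  The
  default scratch geometry uses a 500 µm gap.
- *Nuclear intensity* is the exact mean of intensity pixels under each
  label.

## Synthetic generators

All generators are deterministic functions of an integer seed; feature
parameters are drawn from dedicated `SeedSequence([seed, stream])` streams
so a reference cohort and a treatment time course built from the same specs
share their feature model — this is what makes planted treatment effects
recoverable by clocks trained on the reference cohort.

- **Methylation**: beta = clip(baseline + slope·age + N(0, σ), 0, 1); by
  default 2 000 CpGs of which 500 age with |slope| ∈ [0.001, 0.004]/year
  (i.e. 4–16% per 40 years, straddling the 10% call threshold), noise
  σ = 0.03, 200 samples aged 1–94.  Baselines are constrained so the
  noiseless value never clips, keeping planted slopes exactly linear.
- **Expression** (log2 scale): 1 200 genes, 300 aging (half linear drifts
  of 0.01–0.03 per year, half switches as described above), noise σ = 0.3.
- **Time course**: four arms (negative control, failed, transient, complete
  reprogramming) × 6 donors (ages 38–53) × 3 timepoints.  Treatment
  subtracts a per-arm rejuvenation (defaults 0 / 10 / 30 / 38 years, the
  complete arm resetting to approximately age zero) from the age at which
  age-linked features are evaluated, after the baseline timepoint; ages are
  clamped at zero with a warning.  Identity genes follow their archetype
  (down-and-back, up-and-back, or flat) in the transient arm, stay flat in
  control arms, and are repressed at the end of the complete arm.
- **Regulatory elements**: one promoter (within 1 kb of the TSS) and one
  enhancer (within 1 Mb) per gene, with fibroblast/iPSC activity states;
  element CpGs gain 0.5 beta in states where an enhancer lost activity.
- **Imaging**: wound masks advance the edge by round(speed·t/pixel) per
  frame with salt-and-pepper noise; cell masks are non-overlapping ellipses
  with recorded axes, rotation and intensity.

These sizes are the package's own desk-scale defaults: large enough that
clock training and selection behave like the full-scale analyses (hundreds
of informative features, realistic multiple-testing burden), small enough
that the complete demo pipeline runs in about two minutes on one CPU.

## Numerical choices

- Per-gene Pearson statistics, OLS slopes, and group means are vectorized
  over the full matrix; p-values come from exact t / normal / hypergeometric
  distributions, not permutation.
- Elastic-net and random-forest fits use fixed seeds everywhere; repeated
  cross-validation uses seeded fold generators, so all reported errors are
  reproducible bit-for-bit.
- File outputs are written atomically (temp file + rename) and hashed
  (SHA-256) into the run manifest; re-running a configuration reproduces
  identical hashes.

## Limitations

- The generators are deliberately simple: independent Gaussian noise, no
  probe-level artifacts, no batch structure beyond location/scale shifts,
  no correlation between CpGs beyond their shared age dependence.
  Estimator performance on this model is an upper bound on real-data
  performance.
- `batch_adjust` is moment matching per gene, not empirical-Bayes batch
  correction; it suffices for the location/scale shifts the generator
  produces but is not a ComBat replacement on real multi-batch data.
- Rejuvenated-gene calling uses a rank-sum test on small per-arm sample
  sizes; with the default 6 donors its power is limited and the default
  demo reports calls driven by the planted shift magnitude rather than
  borderline significance.
- The roundness estimator assumes roughly convex, ellipse-like cells; it
  will under-report the elongation of strongly curved or branched shapes.
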