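# Methods

This note records the models, defaults and design decisions behind
`triaxis`, and what the synthetic-fixture results do and do not show
about real data.

## Expression containers and preprocessing

All tables are features × samples (`ExpressionMatrix`), with a
per-sample niche annotation (LE/IT/CT/PAN/MVP/WHOLE/LEUKO) and one
modality per matrix. Protein zeros are treated as missing-at-threshold
(label-free MS zeros are detection failures) and tracked in a boolean
mask; RNA/count zeros are observations.

Preprocessing follows the label-free proteomics convention:

- Technical replicate pairs are averaged; when exactly one value is
  missing the observed value is taken; both missing stays missing.
- Presence filter: keep a feature if it is detected in ≥ 60% of the
  samples of **at least one** niche group. The all-groups reading would
  discard niche-exclusive proteins, which are precisely the markers of
  interest; a config switch (`presence_rule`) selects it if wanted.
- Imputation: log2 transform; per sample column with observed mean μ and
  SD σ, each missing cell ← N(μ − 0.3σ, (1.8σ)²). The (0.3, 1.8)
  pairing is used exactly as configured by default even though the
  common Perseus convention pairs downshift 1.8 with width 0.3;
  `perseus_convention: true` flips them. A width of 1.8σ makes imputed
  values noisy, which is visible in the marker screen's power on
  heavily-missing features.
- Geometric-mean centering: each column is scaled so the geometric mean
  of its positive entries hits the target (10^7 protein intensity,
  2.5 TPM). Rank-based scores are invariant to this per-sample scalar;
  it matters for the tree models, which consume absolute values.
- Region markers: for each feature and niche, two-sided Welch t-tests
  against every other niche; a marker must have the larger mean and
  p < 0.01 in **every** comparison. Welch is used rather than a pooled
  t because group sizes and variances differ; the choice is recorded,
  not prescribed by the source convention.
- Sample outlier flags: OLS of spectra-identified vs total-identified
  features; flag Cook's distance > 4/n or leverage > 2p/n (p = 2).
  Exact fits (zero residual variance) are defined to have Cook's
  distance 0.

## ssGSEA and the statistical kernel

The single-sample score ranks a sample's features ascending (average
ties, so any strictly monotone transform of the abundances gives the
same score), then walks features from highest to lowest rank
accumulating `P_in − P_out`, where `P_in` is the rank^α-weighted
empirical CDF over set genes (α = 0.25, the GSVA-style default) and
`P_out` the uniform CDF over non-set genes. Normalization, when
requested, divides the whole score matrix by its global max − min, so
orderings within and across samples are unchanged. The implementation
is validated against an O(N²) brute-force transcription of the
definition to 1e-9.

Preranked GSEA uses the classic weighted Kolmogorov–Smirnov running sum
(max deviation); the null is random gene sets of matched size; NES is
ES divided by the mean |null ES| of matching sign. The permutation
p-value is two-sided against the full null on |ES| with add-one
smoothing: this keeps the 1/(n_perm+1) floor and a uniform null
distribution, which a same-sign-only denominator cannot provide.

The permutation linear fit enumerates all n! permutations of y when
n! ≤ n_perm (p = exact fraction of permutations with |slope| at least
the observed; the identity permutation makes p ≥ 1/n!), else draws
n_perm random permutations and uses (1+k)/(B+1). The robust fit prunes
residuals outside the 1.5·IQR fence of an initial OLS and re-fits with
HC2 standard errors and a t reference (the defaults of R's
`lm_robust`). Under a clean Gaussian null this two-stage procedure is
mildly anti-conservative (≈3–4% rejections at α = 0.01, n = 30): the
pruning tightens residuals. It is used as a screening device, not for
calibrated inference, and the test suite documents the actual rate.

ROC analysis computes AUC by the Mann–Whitney identity (ties get half
credit) and picks the observed cutoff maximizing Youden's J under
"positive iff score ≥ cutoff", preferring the smallest cutoff on ties.
Survival comparisons use lifelines' product-limit estimator and
two-group log-rank; survival binning is "high" = score ≥ mean.

## Signature selection

The screen is: (i) keep sets with ≥ 20 genes present in both the
protein and RNA matrix; (ii) ssGSEA in both modalities; (iii) keep sets
whose coherence — the fraction of member genes whose expression
regresses on the set's own score with slope p < 0.01 — exceeds 0.4 in
both modalities; (iv) per surviving set, train boosted-stump regressors
(eta 0.1, subsample 0.9, max depth 1, 200 rounds, squared error; the
round count is a package default, deterministic with no early stopping)
mapping expression to the score in each modality; (v) keep sets whose
two models, applied to an external paired cohort, give predictions that
pass the robust fit at p < 0.01. The concordance fit is between the two
prediction vectors, not against a common truth. Genes absent at
inference time are filled with the training median — the least
informative fill for a tree ensemble that requires the full feature
vector.

## CT-niche deconvolution

Synthetic training mixtures are built from a counts compendium with one
source sample per compartment (CT, PAN, LE, MVP, LEUKO) drawn uniformly
per mixture; CT content uniform on [0.2, 0.8]; the remaining mass split
by a flat Dirichlet over the other four. Mixing uses a hierarchical
multinomial — compartment totals ~ Multinomial(total, proportions),
then per-compartment gene counts ~ Multinomial(n_c, source gene
frequencies) — which is distributionally identical to resampling a
concatenated "expanded count" label vector without materializing it
(verified against a literal label-resampling oracle). The default
mixture size is 10^7 counts; the test suite and benchmarks use 10^5
(the package's scaled-down problem size) with the 202-mixture cohort
and 80/20 split (test size floored).

Eleven level-1 models (whole-mixture score, 5 proportions, 5 source
scores; eta 0.2, subsample 0.8, depth 1, 300 rounds) feed a level-2
model of the CT-specific activation, defined as the CT source score
divided by the CT content. The level-2 model is trained on level-1
**predictions** (stacked generalization, matching deployment), and uses
depth-3 trees: its target is a ratio, which an additive depth-1
ensemble cannot represent; the level-1 models stay depth 1. All ssGSEA
targets inside the stack are unnormalized so training and inference
share one scale regardless of batch composition.

Two readouts are exposed. `predict` returns the per-unit-content
CT-specific score (the training target); `predict_ct_activation`
multiplies it by the predicted CT proportion, giving an estimate of the
CT compartment's own score. The second is the content-invariant
quantity: by the training identity (target × CT content = CT source
score) its truth does not change when only the contaminating
composition changes, so it is the right readout for cross-sample
comparison and for quantifying infiltrate robustness. The interference
experiment holds CT content fixed at 0.5 while the contaminant
complement shifts from an even PAN/LE/MVP blend to leukocytes (0→50%),
and compares mean relative drifts: the content-corrected activation
drifts about a third as much as naive whole-sample ssGSEA at the
scaled-down training size, while the raw per-unit-content output —
whose prediction inherits CT-proportion estimation noise — does not
show a comparable advantage at this scale.

## Single cells and the drug screen

Cells under 10,000 total UMIs are discarded (strict less-than);
survivors are scored per cell. Group assignment z-scores the two axis
signatures across cells: KRAS-high requires z_K > 0.5 and
z_K − z_M > 0.5, MYC-high symmetrically, everything else Central. The
threshold-plus-margin rule and both constants are package choices (the
underlying three-group structure does not come with a published cut);
recovery is assessed against planted labels only. Phenotype programmes
are compared across groups by Kruskal–Wallis plus BH-corrected pairwise
rank-sum tests — rank tests because per-cell scores are heavy-tailed.

The drug screen ranks lines by model-inferred signature activation
(not raw ssGSEA), contrasts the bottom and top activation quartiles
(nearest-rank boundaries; ties expand the group; a config option
instead contrasts the bottom quartile against the upper 75%), and calls
a drug significant only under the full conjunction: both groups ≥ 4
members, one-way ANOVA p < 0.05 (with two groups this equals a pooled
t-test), |mean DSS1 difference| > 0.1, and at least one group mean
DSS1 < 0.1. The plate screen normalizes each well to its condition's
reference-well mean, averages replicates per condition, and reports
mean viability and the hypoxic-minus-normoxic differential.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed). A regional
cohort has one sample per tissue niche per patient plus a WHOLE column
that is a convex (Dirichlet-weighted) combination of that patient's
niche profiles. Baseline log2 abundance is N(7, 2); planted programme
genes sit at N(9, 1) — regional markers are, by selection, proteins
quantified reliably across niches. Each niche up-shifts its programme
by 2 log2 units; PAN scales with a latent hypoxia level (U(0.7, 1));
the two CT programmes share a CT baseline component and are modulated
by a latent axis u ∈ [−1, 1] with myc = (1+u)/2, kras = (1−u)/2
(+ small noise), so their anti-correlation and mutual exclusion hold by
construction: shift = effect · (0.35 + 0.65 · level). Tissue niches
carry graded leukocyte infiltrate (highest around MVP), and the LEUKO
compartment has a globally distinct baseline plus strong expression of
the immune programme **and** of both axis programmes — proliferating
immune cells genuinely express MYC/RAS target genes, which is exactly
why infiltrate interferes with whole-sample axis scores and why the
LEUKO surrogate is part of mixture training. Protein dropout is
logistic in log2 abundance (midpoint 4.5, scale 1), giving
missing-not-at-random left-censoring around 16% at defaults. External
validation cohorts and cell-line fixtures can reuse an existing gene
universe (baselines and programme memberships) while redrawing samples,
the way real cohorts share biology but not patients.

Cell-line fixtures draw independent uniform axis levels per line; DSS1
for MYC-axis drugs follows a sigmoid in the MYC level (sensitive only
in MYC-high lines), KRAS-axis drugs are uniformly resistant, null drugs
are flat at a low mean; survival times are exponential with hazard
0.03·exp(1.3·kras), censored at 60 time units. Single cells come from
three populations (35/35/30%) with mutually exclusive axis up-shifts of
2.5 log2 and log-normal library sizes (median 15,000, σ 0.35), so
roughly a tenth of cells fall under the UMI bar.

What passing these fixtures shows: the implementations recover planted
structure of realistic effect size under realistic noise, missingness
and count sampling, with calibrated nulls. What it does not show:
robustness to batch effects, platform differences, ambient RNA or
doublets, annotation errors, or biology outside the planted model —
none of which the generators emulate.

## Problem sizes and numerical choices

The test suite and the reproduction script run reduced problem sizes
chosen as the package's benchmark scale: 150–202 mixtures at 10^5
counts (vs the 10^7 default), compendia of 20 samples per niche at
depth 10^6, cohorts of 8–20 patients at 1,000–2,000 genes, 500–1,000
Monte-Carlo trials for calibration checks. Because the log-normal
baselines are heavy-tailed (a few genes carry much of the count mass),
single-universe benchmark estimates are lumpy; the deconvolution
benchmark therefore replicates its whole experiment over three
independent gene universes and aggregates. Boosted models run
single-threaded with fixed seeds; every CLI stage is byte-reproducible
under a fixed `--seed`. Degenerate inputs (constant targets, zero
margins, empty groups, all-zero columns) raise typed errors rather than
propagating NaNs; ties are broken by documented deterministic rules
(average ranks in scoring; abundance-then-id in feature selection;
smallest cutoff in ROC; tie expansion in quartile groups).

## Known limitations

- The cluster-driver statistic (Welch t + BH between the two clusters)
  is a declared stand-in for sub-pathway-level driver discovery; it is
  not asserted equivalent to any specific published tool.
- The robust two-stage fit is anti-conservative under the null (above);
  its p-values gate screens rather than estimate error rates.
- The raw per-unit-content CT-specific readout is noisy at the
  scaled-down training size; content-corrected activation is the
  recommended cross-sample quantity.
- Log-rank comparison is limited to two groups; no interval censoring.
- The mean-split survival binning discards within-group ordering; at
  small cohort sizes (n ≲ 50) its power against a hazard ratio of ~2 is
  modest, and individual simulated cohorts can fail to separate.
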