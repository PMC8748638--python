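# triaxis

Glioblastoma is not one tissue: a resected tumour mixes histologically
distinct niches — leading edge (LE), infiltrating tumour (IT), cellular
tumour (CT), pseudopalisading cells around necrosis (PAN) and
microvascular proliferation (MVP) — plus a variable leukocyte
infiltrate. `triaxis` implements a niche-resolved expression analysis
pipeline around a three-axis model of intra-tumoral heterogeneity: a
MYC-targets-high proliferative programme and a KRAS-targets-high
migratory programme that are mutually exclusive within the cellular
tumour, crossed with a hypoxia gradient. It is aimed at computational
biologists working with regional proteomics/transcriptomics, bulk RNA
cohorts, single-cell data and pharmacotranscriptomic screens.

The pipeline covers:

- **Preprocessing** for label-free proteomics and TPM tables: technical
  replicate merging, a 60%-within-a-group presence filter, log2 +
  downshifted-Gaussian imputation (downshift 0.3, width 1.8),
  geometric-mean centering (10^7 for protein, 2.5 for TPM), and an
  all-pairwise Welch region-marker matrix at p < 0.01.
- **Single-sample gene-set scoring (ssGSEA)**: per sample, rank features
  ascending with average ties; the score of set *S* is
  Σ_i [P_in(i) − P_out(i)], where P_in accumulates rank^α weights over
  set genes and P_out the uniform step over non-set genes (α = 0.25).
- **Signature selection**: sets with ≥ 20 genes in both modalities, a
  "signature coherence" gate (fraction of member genes whose expression
  fits the set's own score with p < 0.01; threshold 0.4 in both protein
  and RNA), per-signature boosted-stump regressors
  (eta 0.1, subsample 0.9, depth 1) that infer the score from
  expression, and a cross-modality concordance test on an external
  paired cohort (robust IQR-pruned fit between the two model outputs,
  p < 0.01).
- **CT-niche deconvolution**: synthetic count mixtures (CT content
  uniform on [0.2, 0.8]; PAN/LE/MVP/LEUKO completing the unit) feed 11
  level-1 boosted models (whole-mixture score, 5 proportions, 5 source
  scores) and a level-2 model of the CT-specific activation, defined as
  the CT source score divided by the CT content.
- **Statistical kernel**: preranked GSEA with NES, permutation linear
  fits (exhaustive when n! fits the budget; 5000 permutations
  otherwise), robust IQR+HC2 fits, ROC with Youden cut-point
  optimisation, 2×2 χ², Kaplan–Meier/log-rank with mean-split binning
  ("high" = score ≥ mean).
- **Single-cell axis assignment** (UMI ≥ 10,000; z-threshold three-group
  rule) and an **axis-stratified drug screen** (activation quartiles;
  significant iff both groups have ≥ 4 members, ANOVA p < 0.05,
  |ΔDSS1| > 0.1 and at least one group mean DSS1 < 0.1).

A synthetic-data module generates regional cohorts, count compendia
with a leukocyte compartment, single-cell populations and cell-line
drug/survival fixtures with planted ground truth, so every stage is
testable without any external download.

## Worked example

The `analysis/` directory holds the numbered study drivers. After

```bash
python analysis/01_simulate_cohorts.py     # writes results/data/
python analysis/05_deconvolve_ct.py
```

the deconvolution driver prints (seed 7):

```
trained on 162 mixtures, tested on 40
test-split metrics: {'r2_whole_score': 0.949, 'r2_prop_CT': 0.915,
                     'r2_score_CT': 0.858, 'pearson_r_ct_specific': 0.944}
leukocyte interference: naive ssGSEA drifts 12.3%, content-corrected CT
activation 4.1% (ratio 0.34)
KM split of the 150-patient cohort by inferred KRAS-targets activity:
log-rank chi2 = 10.86, p = 0.0010 (high n=85, low n=65)
```

Reading this: the level-1 model recovers the true CT fraction of held-out
mixtures with R² = 0.915 and the level-2 CT-specific KRAS-targets score
correlates with its ground truth at r = 0.944; raising the leukocyte
fraction of a bulk from 0 to 50% at fixed tumour content moves the naive
whole-sample ssGSEA score by 12% of its value but the content-corrected
CT activation by only 4%; and splitting a simulated 150-patient cohort
at the mean inferred KRAS-targets activation separates survival
(log-rank p = 0.001), as expected when the planted hazard increases with
the KRAS-like level. The other drivers cover marker recovery
(`02`, 98.5% of planted programme genes), the signature screen (`03`,
6/6 planted signatures selected, 0/50 decoys), axis structure (`04`,
KRAS-vs-MYC slope −0.91, permutation p = 0.0002 within CT), single-cell
assignment (`06`, adjusted Rand 1.0, 0% double-high cells) and the drug
screen (`07`, 6/6 planted MYC-axis drugs called, no false positives).

There is also a thin CLI (`triaxis simulate/preprocess/score/axes/
train-deconv/infer-ct/survfit/sc/drugscreen/platescreen`); every stage
is byte-reproducible under a fixed `--seed`.

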