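# dsvpipe

Analysis pipeline for **germline deletion structural variants (DSVs)** in
case/control cancer cohorts: from a deletion-call VCF to cancer-risk
feature selection, immune-expression correlation, prognostic stratification
and causal discovery. The package also ships a synthetic-cohort generator
with planted, recoverable effects, so every estimator has a
parameter-recovery test without any external data.

## Who it is for

Statistical-genetics and bioinformatics researchers studying how common
germline deletions (here 500–10,000 bp autosomal events called from WGS)
relate to cancer risk, family cancer history (FCH), the tumor immune
microenvironment, and recurrence-free survival (RFS).

## What it computes

- **Preprocessing** (`dsvpipe.preprocess`) — read `SVTYPE=DEL` VCF records,
  apply the retention filter (autosomal; 500 ≤ length ≤ 10,000 bp; folded
  minor allele frequency ≥ 0.05; carried by ≥ 1% of each cohort), build the
  samples × DSVs binary carrier matrix (carrier ⇔ ≥ 1 deleted copy), and
  annotate DSVs with overlapping genes (half-open interval logic).
- **Risk model** (`dsvpipe.attention`) — an attention-weighted classifier:
  each sample's deletion vector x ∈ {0,1}^m is embedded as
  r = Σ_j x_j·W_j·E_j with a learned scalar weight W_j and embedding row
  E_j per deletion, followed by an MLP with softmax output, trained with
  class-weighted cross-entropy. Deletions with **W_j > 0** after training
  are the cancer-risk-associated set. Benchmarked against MLP / linear SVM
  / logistic regression / random forest under stratified 5-fold CV, plus
  PCA projection and Jaccard-average-linkage clustering of selected DSVs.
- **Association statistics** (`dsvpipe.association`) — per-gene carrier
  2×2 spectra with odds ratios (Woolf CIs, Haldane–Anscombe correction),
  two-sided Fisher exact tests, continuity-corrected chi-square,
  Benjamini–Hochberg FDR, FCH × cancer analysis, FCH-stratified per-gene
  tests, and cohort-characteristics tables.
- **Immune correlation** (`dsvpipe.immune`) — per-gene min–max expression
  scaling, the point-biserial correlation
  r = (ȳ₁−ȳ₀)/s_y · √(n₁n₀/n²) for every (DSV, gene) pair, selection at
  |r| > 0.3, and hypergeometric enrichment over six immune functional
  categories.
- **Prognosis** (`dsvpipe.prognosis`) — a linear ranking survival SVM
  (½‖w‖² + γ Σ hinge over comparable pairs) ranks deletions for recurrence
  timing; univariate Cox log hazard ratios split them into
  recurrence-associated (log HR > 0) and non-recurrence-associated groups;
  patients carrying more of the former than the latter form the
  poor-prognosis stratum G1; separation is tested with Kaplan–Meier curves
  and the log-rank test.
- **Causal discovery** (`dsvpipe.causal`) — stable PC algorithm with
  Fisher-z partial-correlation tests, v-structure orientation and Meek
  rules, yielding a CPDAG over {deletions, immune genes, RFS} and
  deletion → gene → RFS mediation paths.

## Worked example

`examples/` holds one short script per capability. For instance,
prognostic stratification (`python examples/05_prognostic_stratification.py`):

```
patients: 300, observed recurrences: 226
planted DSV DSV00000 in SVM top 10: True

top-ranked deletions with Cox log HR and group:
  dsv_id  log_hr     p                     group
DSV00000   1.345 0.000     recurrence-associated
DSV00036  -0.108 0.625 non-recurrence-associated
...
G1/G2 sizes: {'G2': 239, 'G1': 61}; log-rank statistic = 34.23, p = 4.91e-09
```

The deletion planted with log HR = 1.2 is recovered at the top of the SVM
ranking with a Cox estimate of 1.35, and the G1/G2 count rule separates the
survival curves decisively (log-rank p ≈ 5·10⁻⁹).

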