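# Methods

This note records the models implemented in `dsvpipe`, the defaults and why
they were chosen, what the synthetic-cohort generator does and does not
emulate, and the numerical conventions that matter for reproducing output.

## Coordinates and filtering

A deletion record stores `start` (1-based first deleted base, the VCF POS)
and an exclusive `end` equal to the VCF `END`, so that
`length = end − start`. This convention is fixed by two worked examples
that the test suite asserts: chr7:104,473,711–104,474,263 is 552 bp and
chr7:26,241,421–26,245,980 is 4,559 bp. Gene overlap uses half-open
interval logic: a deletion whose exclusive end coincides with a gene start
does not overlap it. Interval lookup is an interval tree (sub-linear per
query).

The retention filter keeps a deletion when it is (i) autosomal, (ii)
500–10,000 bp, (iii) has folded minor allele frequency ≥ 0.05 computed over
the combined cohort with missing genotypes removed from the denominator,
and (iv) is carried by ≥ 1% of the cancer cohort **and** ≥ 1% of the
non-cancer cohort. The allele-frequency clause of the source protocol is
ambiguous between combined and per-population readings; both thresholds are
parameters (`FilterParams`), with the combined-MAF + per-cohort-carrier
reading as default. Rejections are tallied against the first failing
criterion. Missing genotypes count as non-carriers in the carrier matrix (a
conservative choice, logged).

## Attention-weighted risk model

The classifier scores a binary deletion vector x of length m as
`r = Σ_j x_j W_j E_j` (an e-vector), then `softmax(MLP(r))` over
{cancer, non-cancer}. W is the per-deletion attention weight whose sign
drives feature selection; W and E are coupled by scale (doubling W and
halving E leaves r unchanged), which is why selection uses the sign, not
the magnitude, of W.

Architecture and training defaults, all configurable via `Hyperparams`:
embedding size e = 32; hidden layers (64, 16) with ReLU; Adam at learning
rate 10⁻³; up to 200 epochs of batch-32 minibatches; early stopping on a
10% validation split with patience 20; inverse-frequency class weights in
the cross-entropy (the emulated cohorts are ~1:2.6 imbalanced and
sensitivity is a headline metric). W is initialised uniform on [0, 0.1] —
small and positive so that "positive weight" is informative rather than an
artifact of a sign-symmetric initialisation — and nothing constrains W
during training; E is Gaussian with variance 1/e. The network is small and
tabular, so it is implemented directly in numpy (manual backprop); training
is deterministic given the seed.

Cross-validation is stratified 5-fold; AUC is rank-based, and sensitivity /
specificity are evaluated at probability cut-off 0.5 with cancer as the
positive class (the cut-off is a parameter; no calibration is attempted).
Hierarchical clustering of selected deletions uses Jaccard distance on
binary carrier profiles with average linkage (both configurable); the
distance/linkage pair is a design choice — the source protocol names the
procedure but not the metric.

## Association statistics

2×2 tables are laid out rows = exposure, columns = group. The two-sided
Fisher exact test uses the minimum-likelihood rule (sum of hypergeometric
probabilities ≤ that of the observed table, tolerance factor 1 + 10⁻⁷),
delegated to scipy and verified in the test suite against an independent
brute-force enumeration oracle. The continuity-corrected chi-square is
`N(max(|ad−bc|−N/2, 0))²/(r₁r₂c₁c₂)` with the correction clamped at zero.
Odds-ratio intervals are Woolf (log-normal); any zero cell triggers the
Haldane–Anscombe +0.5 correction (flagged), and a zero diagonal leaves the
OR undefined. Benjamini–Hochberg adjustment is applied within each analysis
family (gene spectrum; each FCH stratum; each category-enrichment table)
separately. Note that BH step-up is not idempotent — re-adjusting adjusted
p-values inflates them — so only monotonicity and adjusted ≥ raw are
asserted as invariants.

Characteristics tables select, per 2-level covariate, the Yates chi-square
when every expected count is ≥ 1 and the Fisher exact test otherwise
(threshold configurable). The ≥ 1 rule, rather than the classical ≥ 5 rule
of thumb, is deliberate: the continuity correction keeps the chi-square
usable at small expected counts, and this choice reproduces the reference
worked examples the tests assert (KRAS p = 0.3245, mucinous histology
p = 0.707, both continuity-corrected chi-square at min expected ≈ 3).

## Immune-expression screen

Expression is min–max scaled per gene across samples; constant genes map
to zero and are flagged. The point-biserial correlation is computed by the
group-means formula with the population (divide-by-n) standard deviation,
which is algebraically the Pearson correlation of y with 0/1-coded x — the
identity is asserted to 10⁻¹² against an independent Pearson computation.
Because r is invariant under positive affine rescaling of y, the screen is
unaffected by normalization; it is still applied so reported values live on
the panel's [0, 1] scale. Selection uses |r| > 0.3 by default (both signs
are biologically meaningful: a deletion can raise or depress expression);
a positive-only mode is available. Category enrichment per deletion is the
hypergeometric upper tail of the selected genes' category counts given the
panel composition.

## Prognostic stratification

The survival SVM is the linear ranking (comparable-pairs) formulation:
minimize ½‖w‖² + γ Σ max(0, 1 − w·(x_i − x_j)) over pairs where sample j
recurred strictly before sample i's observed time. `w·x` is a
survival-time score, so recurrence-accelerating deletions get negative
coefficients. The convex primal is solved with L-BFGS-B using the hinge
subgradient; the objective is recorded at accepted iterates and is
non-increasing (the line search only accepts decreasing steps). γ defaults
to 1.0. Feature importance is |coefficient| with ties broken by column
order; the size k of the selected set is a parameter, not a constant.

Univariate Cox fits use the partial likelihood with Efron tie handling
(lifelines); the suite verifies the estimator against a closed-form toy
problem (β̂ = ln((1+√17)/2)) and against direct maximisation of the
explicit partial likelihood on small tie-free datasets. A deletion is
recurrence-associated iff its log HR is strictly positive; an exact zero
ties to the better-prognosis side. Patients are G1 iff carried
recurrence-associated deletions strictly outnumber non-recurrence-associated
ones (ties → G2, the strict reading of "more than"). Kaplan–Meier and the
two-group log-rank test come from lifelines and are checked against
hand-computed product-limit and (O−E)²/V examples.

## Causal discovery

The PC implementation uses the stable (order-independent) skeleton: per
conditioning-set size, adjacency sets are snapshotted before any edge
removal. Conditional independence is the Fisher-z test on partial
correlations obtained by inverting the correlation submatrix;
z = √(n−|S|−3)·atanh(ρ̂). Binary deletion indicators enter the same
Gaussian test as numeric 0/1 — the pragmatic convention of common PC
implementations. Orientation declares v-structures from separation sets
(conflicts leave the edge undirected, logged) and applies Meek rules 1–4 to
closure, refusing orientations that would close a directed cycle. α
defaults to 0.05. RFS enters as the observed event time of
event-observed samples only; censoring-aware independence testing is out of
scope. Mediation paths deletion → gene → RFS are reported as "directed"
when both hops are oriented and "compatible" when an undirected hop could
be oriented that way within the equivalence class.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: a cancer
cohort (default 192; four cancer types in the emulated proportions) versus
a non-cancer cohort (default 499), autosomal deletions with lengths uniform
on [500, 10,000] bp, diploid genotypes under Hardy–Weinberg equilibrium per
cohort. Planted risk deletions specify a **carrier** odds ratio and a
control allele frequency; the case allele frequency is solved from the
carrier odds (an infinite OR is the only way to demand a case carrier
frequency ≥ 1, and is rejected). Background deletions share one frequency
across cohorts, drawn uniform on [0.05, 0.35]. FCH is Bernoulli with
control prevalence 0.435 and a configurable case/control odds ratio
(default 1.89). Expression is standard-normal noise plus β·carrier for
planted pairs; categories are assigned round-robin over the six immune
functions. Survival is exponential: hazard λ₀·exp(Σ log-HR·carrier) with
λ₀ = 0.02/month and independent exponential censoring at 0.01/month —
time scales typical of multi-year recurrence follow-up, and closed-form
checkable. All stages draw from substreams spawned deterministically from
one seed.

What the generator does **not** emulate: read-level data and genotyping
error, linkage disequilibrium and population structure, relatedness,
batch effects in expression, non-proportional hazards, informative
censoring, or any dependence between planted effects. Passing
parameter-recovery tests therefore demonstrates estimator correctness
under the generating model, not robustness to real-data pathologies.

## Problem sizes and calibration studies

Recovery studies use the sizes at which the corresponding effects are
identifiable at desk scale: the attention study plants 20 OR=3 deletions
among 300 at 600+600 samples; survival studies use 300 patients with 51
deletions; PC chain recovery uses n = 2000 per run. Null-calibration
studies run 500 replicates each. The Fisher calibration deserves a note:
exact-test p-values are conservative by construction (discrete support
with an atom at p = 1), so KS-uniformity holds only in the large-sample
regime where the conditional support is dense; the calibration uses
1500 samples per arm for that reason. Log-rank and Fisher-z calibrations
are insensitive to this and run at modest sizes. The Fisher-vs-enumeration
equivalence is exhaustive for table totals ≤ 16 and randomly sampled
(seeded) for totals up to 60.

## Known limitations

- The attention model's positive-weight rule selects liberally (most
  weights stay positive on well-separated data); it recovers planted
  effects but is not a sparse selector.
- Survival-SVM comparable pairs grow quadratically in the event count;
  cohorts beyond ~10³ samples need subsampling of pairs.
- The PC implementation targets small variable sets (deletions of interest,
  a gene panel, one outcome), not genome-wide graphs.
- Cox fits on deletions with very few carriers can sit near monotone
  likelihood; such deletions are dropped from the partition with a warning
  rather than reported with unstable estimates.
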