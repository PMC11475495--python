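# Methods

`gatsurv` implements a survival-prediction protocol for multi-omics cancer
cohorts: patients are nodes of a correlation graph, a multi-head graph
attention network (GAT) maps each patient's screened molecular profile to a
scalar risk score, and the network is trained by maximizing the Cox partial
likelihood of the observed, right-censored survival outcomes. This note
documents the model, the synthetic cohort generator that stands in for a
TCGA-style NSCLC cohort, the numerical choices, and what the package's tests
do and do not establish.

## The model

**Hazard model.** Each patient `i` has hazard `h(t | x_i) = h0(t) exp(r_i)`
where the risk score `r_i` is produced by the network. The baseline hazard
`h0` is never estimated: training minimizes the negative log Breslow partial
likelihood, normalized by the number of events,

    L = -(1/D) sum_{i: event} [ r_i - log sum_{j in R(t_i)} exp(r_j) ],

with risk sets `R(t)` formed from training-fold nodes only (subjects censored
exactly at `t` stay in the risk set at `t`). The loss is invariant to adding
a constant to all risks, so the network's output needs no link function.

**Network.** Two attention layers over the patient graph. Per head,
attention logits are `e_ij = LeakyReLU(a^T [W h_i || W h_j])` (negative slope
0.2, the canonical choice), normalized by a softmax over the neighborhood
`N_i`, and aggregated as `h_i' = sigma(sum_j alpha_ij W h_j)`. Layer 1 uses
`hidden_dim = 64` units and `K = 4` heads whose outputs are concatenated
(the information-preserving convention for hidden layers; averaging, the
printed `1/K` multi-head form, is available via `head_merge_hidden="mean"`),
followed by batch normalization, ELU, and dropout. Layer 2 emits one value
per head and averages heads into the scalar risk. Dropout (default rate 0.6)
is applied to layer inputs and attention coefficients during training only.
Self-loops are always added to the graph so every node's own features enter
its aggregation; an isolated node reduces to a per-node feed-forward unit.

**Training.** Adam (lr 1e-3, L2 weight decay 1e-5 folded into gradients, the
convention of mainstream deep-learning optimizers), global gradient-norm
clipping at 1.0, at most 200 epochs with early stopping (patience 20) on the
Cox loss of a stratified 20% validation split of the training mask. The
clipping norm, epoch budget and patience are this package's choices. The
whole stack — forward, backward, optimizer — is plain numpy; the backward
pass is exact (verified against central finite differences at relative error
below 1e-4) and every random draw flows from one seeded generator, so fits
are bit-reproducible. The attention is implemented densely (an n x n masked
logit matrix); for cohort-scale graphs this is faster in numpy than
edge-list gather/scatter, and a naive per-neighbor loop implementation
serves as its oracle in the tests.

**Protocol.** Evaluation is transductive stratified k-fold (default k = 5;
k = 10 is a flag): per fold the chi-square screen runs on training samples
only (clinical covariates always bypass the screen), SMOTE balances the
training fold's vital-status classes, the 0.7-threshold correlation graph is
rebuilt over all nodes (training, synthetic, held-out), the network trains
with the loss restricted to training nodes, and held-out nodes — present in
the graph but absent from every loss term, screen, and standardization
statistic — are scored in the same forward pass and summarized by Harrell's
C. Scrambling held-out outcomes provably leaves the trained scores unchanged
(tested). A `screen_global` flag reproduces the screen-before-split variant;
it leaks selection information into held-out folds and is off by default.

## Component conventions

- **Chi-square screen.** Features are binarized strictly above their median
  (ties code 0), cross-tabulated against vital status (Dead = 1), and tested
  with the plain Pearson statistic, no continuity correction, selection at
  p < 0.05 strictly. Zero-margin tables are degenerate (expected counts
  undefined) and never selected. No multiple-testing adjustment by default —
  the screen is deliberately a raw per-feature filter; Benjamini-Hochberg is
  available.
- **Graph.** Pearson correlation between patients across z-scored, screened
  features; an edge requires r >= 0.7 (inclusive), positive correlations
  only — anti-correlated patients are not linked. Column z-scoring removes
  any component shared by all samples, so "within-cluster correlation"
  produces edges only when at least two clusters exist.
- **SMOTE.** `x_syn = x_i + lambda (x_nn - x_i)` with `lambda ~ U[0,1]`,
  k = 1 neighbor and seed 42 by default. Synthetic nodes inherit the base
  sample's (time, event) and are attached to the graph by the same
  correlation thresholding — the reference protocol does not specify either,
  so both are package interpretations. Balancing runs inside training folds
  by default to avoid leakage; a global variant exists for fidelity runs.
- **Ridge Cox.** Newton iteration with step halving on the Breslow partial
  likelihood minus `(lambda/2)||beta||^2`, to an infinity-norm gradient
  tolerance of 1e-8; default penalty 0.1 on z-scored features.
- **Stratification.** The exploratory high/low-risk split applies PCA (95%
  variance retained), drops one of each component pair with |r| > 0.9 (inert
  for exact PCA scores, kept as a guard for other reductions), optionally
  chi-square-screens the components, fits ridge Cox, splits at the median
  risk, and compares groups by Kaplan-Meier and the log-rank test. The
  PCA share and drop threshold are package choices.
- **Harrell's C.** Comparable pairs: earlier time has an event, or tied
  times with exactly one event; tied risks count 0.5. AUC is Mann-Whitney
  with the event indicator as the label and the median-score threshold for
  accuracy — the classification framing is reported separately from C rather
  than equated with it.

## The synthetic cohort generator

The generator emulates the *output* of a preprocessed multi-omics NSCLC
cohort, not the preprocessing itself (no read simulation, no differential
expression internals). Reference design (the defaults): n = 600 patients;
blocks mRNA 1000, miRNA 200, methylation 789, clinical 11 (2000 features);
50 informative omics features (20/10/20) with |beta| ~ U[0.5, 1]; baseline
hazard 0.01 per day; 30% target censoring; six patient clusters with latent
within-cluster correlation 0.85.

Mechanics: a latent Gaussian field per block combines cluster offsets
(weight `sqrt(rho)`) with individual noise. Informative features load with
mixed signs on a per-block *risk-module factor* (weight `sqrt(tau)`,
`tau = 0.6`), and that factor is itself cluster-structured with the same
`rho` — molecular subtypes (clusters) carry most of the prognostic signal,
with individual variation on top. Two design facts motivate this:

1. **Per-feature detectability.** Fifty mutually independent informative
   features would each carry ~2% of the linear predictor's variance; a
   median-binarized chi-square at n = 600 would then have well under 50%
   power per feature. Correlated risk modules (co-regulated pathway genes)
   are both the realistic reading and what makes a marginal per-feature
   screen a sensible tool.
2. **Graph-signal alignment.** A patient-similarity graph helps exactly when
   neighbors have similar hazards. Cluster-structured risk factors make the
   0.7-correlation graph prognostically informative, which is the premise of
   the method being implemented.

Raw values are monotone transforms of the latent field: log-normal for the
expression blocks (per-feature location drawn per block), per-CpG Beta
marginals (a menu of hypo-, hyper- and intermediate-methylation shapes)
mapped through the Gaussian CDF for methylation, and 11 mixed binary /
ordinal / continuous clinical covariates whose category frequencies mirror a
reference NSCLC cohort; age and pack-years enter the hazard weakly (z-scale
coefficient 0.2). The hazard's linear predictor is defined on the z-scored
*feature matrix* (not the latent field), so the stored ground-truth
coefficients refer to exactly the columns downstream code sees. Survival
times are inverse-transform draws from the proportional-hazards model;
censoring is an independent exponential whose rate is set by deterministic
bisection on fixed uniform draws, so the realized censoring fraction hits
the target to within the resolution of n samples and the whole cohort is a
pure function of its config.

**Consequences to keep in mind.** Under the reference design the linear
predictor has a large standard deviation (the risk modules concentrate
variance), so the cohort sits in a strong-signal regime: the true-hazard
C-index is ~0.96 and a well-tuned linear model outperforms the network.
Passing the recovery checks therefore shows the pipeline extracts strong,
module-structured signal through screening, balancing, graph construction
and attention training — it does not show the network beats simpler models,
nor calibrate performance on weak-signal clinical data. Real cohorts also
have batch effects, missingness, non-proportional hazards and informative
censoring, none of which the generator emulates.

## Numerical choices and degenerate inputs

- Softmax over neighborhoods and partial-likelihood denominators use
  max-subtraction; risk-set sums are suffix cumulative sums over
  time-sorted samples with tie groups sharing one Breslow denominator.
- A training mask with zero events defines the loss as 0 with a warning
  (degenerate fold); folds with fewer than two events are skipped.
- Constant feature columns are guarded in z-scoring (unit divisor), rejected
  by the ridge fit, and produce degenerate tables in the screen (skipped
  rather than patched with pseudo-counts).
- Grid search breaks C-index ties toward the smaller hidden width, then
  fewer heads, to keep the selected configuration deterministic.
- Dataset TSVs are written with 17 significant digits and parsed with
  round-trip float precision, so write/read is bit-exact.

## Problem sizes used in the test and acceptance runs

Unit tests run on cohorts of 60–220 samples with tens of features. The
recovery checks use the full reference design (600 x 2000, five folds, both
a signal run and a label-permuted control); determinism is demonstrated on a
200 x 231 cohort with three folds. Oracle suites use 1000 random 2x2 tables,
200 random cohorts of up to 50 subjects for the brute-force concordance
check, and 20 random 10-node graphs for the dense-vs-naive attention check.

## Known limitations

- Transductive only: scoring a genuinely new patient requires rebuilding the
  graph and re-running a forward pass with the stored parameters; no
  inductive predict path is provided.
- Breslow tie handling only (no Efron); fine for continuous synthetic times,
  slightly anti-conservative with heavy ties.
- The dense n x n attention stores O(K n^2) floats; beyond ~5000 nodes an
  edge-list implementation would be preferable.
- The attention-weight feature ranking (summed |W| mass of layer 1) is a
  global saliency, not a per-patient explanation; the gradient-x-input
  alternative is sharper on sparse signals but noisier.
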