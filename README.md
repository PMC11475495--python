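# gatsurv

Survival prediction for multi-omics cancer cohorts with a graph attention
network (GAT) trained on a Cox partial-likelihood loss.

Predicting which non-small cell lung cancer patients are at high risk of
death is harder than any single molecular assay can support: mRNA
expression, miRNA expression and DNA methylation each see a different slice
of tumor biology. This package implements a pipeline that merges such
omics blocks by sample, screens features with a chi-square test of
median-binarized values against vital status, balances deceased/alive
classes with SMOTE, connects similar patients into a correlation graph
(Pearson r >= 0.7), and trains a multi-head graph attention network whose
scalar output per patient is fitted as the log relative hazard of a Cox
proportional-hazards model. Performance is summarized by Harrell's
concordance index under cross-validation, and risk groups are compared by
Kaplan-Meier curves and the log-rank test. A synthetic multi-omics cohort
generator with known ground truth makes every stage testable without any
data download.

It is aimed at computational biologists who want a transparent, fully
seeded, pure-numpy reference implementation of GAT-based survival modeling
— every gradient is hand-derived and checked against finite differences —
rather than a GPU training framework.

## The model

Patients are nodes `i` with screened feature vectors `h_i` and edges between
samples whose correlation exceeds 0.7. Per attention head:

    e_ij     = LeakyReLU(a^T [W h_i || W h_j])          (attention logits)
    alpha_ij = softmax over j in N(i) of e_ij           (self-loops included)
    h_i'     = sigma( sum_j alpha_ij W h_j )            (aggregation)

Layer 1 (64 units x 4 heads, concatenated, batch norm, ELU, dropout 0.6)
feeds layer 2, whose per-head scalars are averaged into the risk score
`r_i`. Training minimizes the negative log Breslow partial likelihood

    L = -(1/D) sum_{i: death} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]

over training-fold nodes with Adam (lr 1e-3, weight decay 1e-5), gradient
clipping and early stopping. Held-out nodes sit in the same graph but never
touch the loss; their risk scores are read from the same forward pass
(transductive protocol).

## Worked example

```python
from gatsurv import (CohortConfig, generate_cohort, screen_features,
                     run_cv, TrainConfig, stratify_km)

config = CohortConfig(
    n_samples=300,
    block_sizes={"mrna": 300, "mirna": 60, "meth": 140, "clinical": 11},
    n_informative={"mrna": 10, "mirna": 4, "meth": 6},
    seed=42,
)
cohort = generate_cohort(config)
print(f"cohort: {cohort.n_samples} patients x {cohort.n_features} features, "
      f"{cohort.outcome.n_events} deaths")

selected = screen_features(cohort, blocks=["mrna", "mirna", "meth"])
print(selected.summary(cohort.feature_block).to_string(index=False))

result = run_cv(cohort, ("mrna", "mirna", "clinical"), k_folds=5, seed=0,
                train_config=TrainConfig(seed=0))
print(f"{result.combination}: mean C-index "
      f"{result.mean_c_index:.3f} +/- {result.std_c_index:.3f}")

strat = stratify_km(cohort)
print(f"median-risk split: log-rank p = {strat.log_rank.p_value:.2e}, "
      f"ridge-Cox C-index = {strat.c_index:.3f}")
```

Output:

```
cohort: 300 patients x 511 features, 210 deaths
block  n_tested  n_selected        min_p   max_p
 mrna       300         169 1.060365e-17 0.04382
mirna        60          39 1.721831e-12 0.04382
 meth       140          79 9.158345e-17 0.04382
mRNA-miRNA-ClinicInfo: mean C-index 0.734 +/- 0.031
median-risk split: log-rank p = 2.53e-46, ridge-Cox C-index = 0.838
```

Reading the numbers: 210 of 300 patients died (30% censoring, the
generator's target); the chi-square screen keeps 287 of 500 omics features
at p < 0.05 (the informative risk modules plus correlated passengers —
every retained max p is below 0.05); five-fold transductive GAT training on
the mRNA + miRNA + clinical combination ranks held-out patients with mean
C = 0.734 (0.5 would be random); and splitting patients at the median
ridge-Cox risk score produces survival curves whose separation is far
beyond chance (log-rank p ~ 1e-46).

The same steps are available from the shell:

```bash
gatsurv simulate --seed 42 --out runs/cohort
gatsurv select runs/cohort --out runs/selected.tsv
gatsurv graph runs/cohort --threshold 0.7 --out runs/edges.tsv
gatsurv cv runs/cohort --blocks mrna,mirna,clinical --folds 5
gatsurv stratify runs/cohort --out runs/strat
```

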