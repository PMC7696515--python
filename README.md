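# tcox

Correlation-dissimilarity-weighted elastic-net Cox regression for selecting
genes whose co-expression pattern differs between tumor and normal tissue.

## The problem

Regularized Cox models (lasso / elastic net) are the standard way to select
prognostic genes from high-dimensional expression data, but they treat every
gene symmetrically. Genes whose *co-expression network* is rewired between
tumor and normal tissue are biologically interesting candidates: a gene that
correlates with one set of partners in healthy tissue and a different set in
the tumor plausibly sits near a disrupted regulatory process. This package
implements a penalized Cox model that encodes exactly that prior.

## The method

Given expression matrices for the two conditions over a shared gene set,
build the gene–gene correlation matrices Σ_T and Σ_N. For gene *j*, let
σ_j^T and σ_j^N be its correlation profiles (correlations with the remaining
*p* − 1 genes, self-correlation excluded). The rewiring of gene *j* is the
angle between the two profiles,

    d_j = arccos( ⟨σ_j^T, σ_j^N⟩ / (‖σ_j^T‖ ‖σ_j^N‖) ) ∈ [0, π],

max-normalized to w_j = d_j / max_k d_k and transformed into a per-gene
penalty factor (default: 1/w_j; five alternative transformations are
available). The factors enter a weighted elastic-net Cox objective

    −ℓ(β)/n + λ [ α ‖w ∘ β‖₁ + (1 − α) ‖w ∘ β‖₂² ],

where ℓ is the Cox partial log-likelihood. Strongly rewired genes get small
factors and are penalized less, so they enter the model more easily; genes
with identical profiles in both conditions (d_j = 0) are excluded from the
support outright. Sample risk is `exp(xᵀβ)` relative to baseline; the
baseline hazard itself is never estimated.

The accompanying evaluation protocol mirrors the benchmark the method was
designed for: repeated 70/30 splits preserving the censoring proportion,
cross-validated λ, dichotomization of test samples at the median fitted
relative risk, a Kaplan–Meier / log-rank comparison of the two risk groups,
and S / NS / NA accounting (significant / not significant / not estimable)
across runs — with unweighted elastic-net and degree-weighted ("hub-like",
"orphan-like") comparator arms.

## Worked example

```python
import numpy as np
from tcox import (SimulationConfig, simulate_dataset, tcox_weights,
                  WeightedCoxnet, median_risk_groups, logrank_test,
                  stratified_split)

study = simulate_dataset(SimulationConfig(seed=0))     # 300+300 samples, 60 genes
weights = tcox_weights(study.tumor, study.normal)      # angles -> 1/w factors

train, test = stratified_split(study.survival, 0.7, seed=0)
model = WeightedCoxnet(train, alpha=0.1, penalty_factors=weights)
res = model.fit(n_lambdas=50, cv_folds=5, seed=0)
print(res.summary())

risks = res.predict_relative_risk(test.X)
high = median_risk_groups(risks)
print(logrank_test(test.time, test.status, high))
```

Output (abridged):

```
Weighted elastic-net Cox regression
==========================================================
n samples                   210
n events                    130
n genes                      60  (excluded: 0)
alpha                       0.1
penalty mode            literal
lambda                  0.05747  (CV-selected)
support size                 39
partial log-lik       -568.4922  (null: -601.2101)
----------------------------------------------------------
gene                      beta        HR    factor
g020                   0.27182    1.3124     1.208
g030                   0.26977    1.3097     1.245
g011                  -0.26247    0.7692     1.202
g001                  -0.24268    0.7845     1.347
...
LogRankResult(statistic=6.9196..., pvalue=0.00852...)
```

The cross-validated λ keeps a broad support (α = 0.1 is ridge-heavy), but
the ten largest coefficients — everything above |β| ≈ 0.1, with penalty
factors near 1 — are exactly the ten rewired signal genes of the generating
truth, and the log-rank p-value shows the held-out risk groups separate.
The trailing near-zero coefficients carry factors around 3–4: the penalty
has already pushed the non-rewired genes toward irrelevance.

A command-line interface wraps the same pipeline for TSV inputs:

```bash
tcox simulate --outdir sim/                # synthetic study + truth file
tcox weights --tumor sim/tumor_expression.tsv --normal sim/normal_expression.tsv --out w.tsv
tcox fit --expr sim/tumor_expression.tsv --clinical sim/clinical.tsv --weights w.tsv --out fit.tsv
tcox benchmark --expr sim/tumor_expression.tsv --normal sim/normal_expression.tsv \
               --clinical sim/clinical.tsv --outdir bench/
```

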