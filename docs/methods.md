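# Methods

## Model

The package fits a Cox proportional-hazards model, h_i(t) = h₀(t) exp(x_iᵀβ),
by minimizing the penalized negative partial log-likelihood

    −ℓ(β)/n + λ [ α ‖w ∘ β‖₁ + (1 − α) ‖w ∘ β‖₂² ],

with risk sets R_i = {j : t_j ≥ t_i} and an elastic-net penalty whose
per-gene factors w come from the tumor/normal correlation-rewiring angle.
Only relative risks exp(xᵀβ) are produced; the baseline hazard h₀ is out of
scope, as nothing in the selection-and-evaluation pipeline needs it.

### Penalty semantics

The default ("literal") parameterization keeps the factors inside both
norms, so the ridge term effectively sees squared factors. glmnet-style
software instead applies factors linearly to both terms with a halved ridge
term, λ Σ_j w_j [α|β_j| + (1−α)β_j²/2]. Which semantics produced a given
published analysis is often not recoverable from its printed formulas, so
both are provided (`penalty_mode="literal" | "linear"`); they coincide at
α = 1.

### Solve routes

For the literal mode the model exploits an exact reduction: substituting
γ_j = w_j β_j and dividing column j of X by w_j yields a standard
unweighted elastic-net Cox problem in γ, solved *without* any internal
re-standardization and back-transformed as β_j = γ_j / w_j. A direct
proximal solve on the original parameterization is retained as an
independent route; the two agree to ~1e−6 on random instances (this is one
of the package's acceptance checks). The linear mode, and any model with a
zero factor (an unpenalized gene, e.g. the `one_minus` transform at w = 1),
always use the direct route, since the reduction would divide by zero.

### Solver

FISTA (proximal gradient with Nesterov momentum) with:

- backtracking line search; the step size decays 10% per iteration so it can
  recover after a conservative backtracking episode;
- gradient-based adaptive restart of the momentum sequence;
- warm starts along the decreasing λ path;
- termination when the max coefficient change drops below `tol` (default
  1e−7, max 10⁵ iterations) *and* the KKT subgradient residual is below
  100·tol — the step criterion alone can report a stalled, not converged,
  point;
- the pure-smooth case (λ = 0, or all thresholds zero) is delegated to
  L-BFGS at tight tolerances, which is the right tool for an unpenalized
  partial-likelihood maximum.

Breslow tie handling is the default, matching the risk-set definition
above; Efron is available behind `ties="efron"`. Gradients use O(n log n)
suffix-sum evaluations with the risk-set ordering cached per solve.

λ_max is the smallest λ whose solution is exactly 0, computed from the KKT
conditions at β = 0 (with α floored at 1e−3 for path construction so the
ridge limit keeps a finite path start). The default path has 100 log-spaced
values from λ_max down to 0.01·λ_max (0.05·λ_max when n < p).

Covariates are centered and scaled to unit variance *before* the weight
rescaling, so penalty factors compare genes on a common scale; coefficients
are reported on the original scale. λ is selected by K-fold cross-validated
partial-likelihood deviance in the Verweij–van Houwelingen form,
−2[ℓ_full(β^(−k)) − ℓ_train^(−k)(β^(−k))], with folds stratified by event
status and re-drawn (boundedly) if a training part has no events.

## Dissimilarity weights

Correlations are Pearson by default — the angle computation operates on
correlation vectors and needs no rank assumptions — with Spearman behind a
flag; whether to correlate raw or log-transformed expression is left to a
preprocessing hook that defaults to identity. Profiles exclude the
self-correlation, which is 1 in both conditions and would only shrink every
angle toward 0. The angle is evaluated in the chord form
2·arcsin(‖û − v̂‖/2), algebraically the arccos of the clipped cosine but
exact at the boundaries: bitwise-identical profiles give exactly 0, never a
~1e−8 rounding angle, and antipodal profiles give exactly π.

Zero-angle genes carry no rewiring signal. Rather than receiving an
arbitrary epsilon-floored factor, they are flagged and excluded from the
model support entirely (coefficient pinned at 0 at every λ) — equivalent to
an infinite penalty and free of tuning constants.

Six factor transformations of the normalized weight w are provided: 1−w,
1−w³, (1−w)³, 1/w, exp(−w³), exp((1−w)³). The default is 1/w, the
transformation that gave the sharpest risk-group separation in the original
colorectal-cancer evaluation of this weighting scheme. All inverting kinds
are non-increasing in w: more rewiring, less penalty.

By default the weights are computed once from the full tumor/normal
expression, mirroring the published pipeline's design in which the weight
construction precedes the survival splits; since the normal cohort contains
no survival information the leakage is indirect at most, but a
train-only-weights flag is available for leakage-sensitive analyses.

## Degree comparators

The hub-like and orphan-like arms weight genes by thresholded
absolute-correlation degree: degree_j = Σ_{k≠j} |σ_jk|·1[|σ_jk| > τ],
normalized by the max; hub factor = 1 − g_j + ε, orphan factor = g_j + ε,
ε = 0.01, τ = 0 (all edges, weighted by |correlation|). This is a
deliberately simple stand-in for published centrality-weighted Cox
software, built so the benchmark has all four arms; it makes no claim of
numerical compatibility with any particular package. The network defaults
to the tumor condition (configurable).

## Evaluation protocol

Each run: censoring-stratified 70/30 split (per-stratum counts rounded to
nearest, exact halves toward train), fit on the training part with CV λ,
median split of the test-set relative risks (ties at the median go to the
low-risk group — an arbitrary but fixed convention required for
reproducibility), two-group log-rank test. Outcomes: S (test p < 0.05), NS
(p ≥ 0.05), NA — the model could not be estimated: empty selected support,
CV failure, non-finite coefficients, or degenerate (constant) risks. NA
runs never abort a batch. The log-rank p-value is the standard two-sided
1-df chi-square. Per-run seeds are derived from the master seed via a seed
sequence, so batches are bitwise reproducible and runs never share seeds.

Kaplan–Meier and the two-group log-rank statistic are implemented directly
from their definitions (product limit; per-event-time hypergeometric
tables) and are cross-checked against lifelines in the test suite.

## Synthetic data generator

The generator emulates the study design, not the marginal distributions of
RNA-seq: two cohorts over a shared gene set, block-exchangeable correlation
(blocks of 10, ρ = 0.6 — a typical co-expression-module strength), and a
set of rewired genes that leave their home block and form a new mutually
correlated block in the tumor condition, so their profiles change while all
non-rewired pairs are untouched; both true matrices stay positive definite
for any ρ ∈ [0, 1). Survival for the tumor cohort follows a proportional-
hazards model with exponential baseline (rate 1e−3/day, i.e. mean survival
1000 days) on a sparse coefficient vector supported on the rewired genes
with alternating signs and magnitude 0.35 per SD of expression (hazard
ratio ≈ 1.4 per SD, a moderate single-gene prognostic effect). Censoring is
administrative-uniform; the horizon is calibrated by bisection on the
simulated event times so the realized censored fraction tracks the target
(default 40%).

Defaults: 300 tumor + 300 normal samples, p = 60 genes, 10 rewired signal
genes. These sizes keep a full four-arm, repeated-split benchmark runnable
on a laptop in minutes while leaving the n ≫ p vs p ≫ n distinction to the
λ-path heuristic.

What passing on this generator does **not** show: robustness to count-like
marginals and mean–variance coupling (a log-normal flag gives skewed
marginals but not library-size artifacts), batch effects, gene-length
biases, or networks rewired more subtly than block reassignment. Expression
is Gaussian because the weighting consumes only correlations.

## Reproduction script sizes

`scripts/acceptance.py` uses 20 simulation replicates for the weight-ranking
and matched-support comparisons, 50 random instances for the solver-route
agreement, 2000 Monte-Carlo replicates (200 per group) for log-rank
calibration, and 12 repeated splits per arm (3 CV folds, 40-value λ path)
for the four-arm benchmark — sizes chosen so the full recomputation stays in
the minutes range while every reported fraction remains meaningful.

## Numerical conventions and degenerate inputs

- Correlation matrices are symmetrized and clipped to [−1, 1]; a
  zero-variance gene is an error naming the gene.
- A zero-norm correlation profile (possible only in degenerate true
  matrices, not in sampled ones) is an error naming the gene.
- All dissimilarities zero (identical conditions) is an error — there is no
  signal to weight by.
- Constant predicted risks make median dichotomization impossible; inside
  the benchmark this is recorded as NA.
- TSV writers use %.17g and readers round-trip parsing, so generator output
  survives a write/read cycle bit-identically.

## Known limitations

- The weighted fit inherits elastic-net behaviour: among highly correlated
  genes the support is somewhat arbitrary; selection frequencies across
  runs are the more stable summary.
- The degree comparators are simplified by design (see above).
- Efron ties use a per-event-time Python loop; fine for thousands of
  samples, not optimized for very large cohorts.
- Cross-validated deviance targets predictive fit, not support recovery;
  matched-support comparisons in the benchmark sidestep this, but the
  CV-selected support size itself can be conservative on weak signals.
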