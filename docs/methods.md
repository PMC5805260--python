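# Methods

This note documents the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic-data generator does and
does not emulate, and the numerical and design choices that were genuinely
open.

## Study design and data model

The package targets paired two-omics designs: a miRNA log-intensity matrix
X (features × samples) and an mRNA matrix Y over the same subjects, with a
binary outcome z. The reference design has 13 cases and 30 controls, seven
of the 43 subjects contributing two technical replicates, and post-filter
feature counts near 396 miRNAs and 327 mRNAs. All expression values are
treated as log-scale intensities; absent detection calls and missing values
are represented identically as missing entries (internally a mask/NaN,
`NA` in TSV files).

## Preprocessing

Fixed order: replicate collapsing → presence/missingness filters → outlier
masking → quantile normalization → kNN imputation. Filters act before
normalization because absence is a detection property of the raw arrays.

- **Replicate collapsing.** Each physical sample becomes the mean of its
  replicate columns over non-missing entries; an entry is missing only if
  missing in every replicate.
- **miRNA presence filter (30%).** A miRNA is dropped only when its
  non-absent fraction is below 0.30 in *both* groups; a feature well
  detected in either group is kept, since group-restricted expression is
  exactly the signal of interest. The complementary reading (drop when
  either group is low) is available as `filter_mode="either"`. A second
  pass drops miRNAs with overall missingness strictly above 40% (applied
  overall, not per group — the per-group variant is not specified anywhere
  and overall is the weaker, safer filter).
- **mRNA filter (50%).** Dropped at 50% missing *or more* (boundary
  inclusive, unlike the miRNA filter's strict inequality — the two rules
  are stated differently and are implemented as stated).
- **Outlier masking (3 SD).** Single pass: per-feature mean and sample SD
  computed once over observed entries; entries strictly beyond 3 SD are set
  missing. No re-estimation after masking — iterative masking would change
  counts silently. A value at exactly 3 SD is kept. Features with fewer
  than 3 observations are skipped and logged.
- **Quantile normalization.** Classic between-array normalization. With
  missing data, each column's empirical quantile function is interpolated
  onto a common grid of length equal to the largest observed count, the
  reference is the across-column mean on that grid, and each observed entry
  maps to the reference at its within-column rank; tied values receive the
  mean of their tied ranks' reference values. Complete columns end with
  identical sorted values, and within-column ranks are preserved.
- **kNN imputation (k = 10).** Feature-space neighbours under a
  root-mean-square distance over jointly observed samples (count-normalised
  so sparsely observed features are not artificially close), unweighted
  mean of the k nearest features observed at the target sample. Entries
  with fewer than k usable neighbours fall back to the feature's own
  observed mean. k = 10 follows the convention of the standard
  expression-imputation implementations; the algorithm's parameters are
  otherwise unspecified in the source analysis.

## Differential expression

Per feature, OLS on [intercept, group] gives the case-minus-control effect
and residual variance s²_g on d_g = n − 2 df. The empirical-Bayes layer
assumes σ²_g follows a scaled inverse-χ² prior (d₀, s₀²) estimated by
moment matching on log s²_g: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess dispersion
var(e) − ψ′(d_g/2) determines d₀ through the trigamma inverse (Newton
iteration), and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). Non-positive
excess dispersion yields d₀ = ∞ (uniform shrinkage to s₀²). The moderated
t uses the posterior variance and d₀ + d_g df. One subtlety documented by a
unit test: when every s²_g is identical the estimator reports d₀ = ∞ with
s₀² equal to the log-scale bias-corrected variance, *not* s²_g itself —
the intuitive "no dispersion ⇒ no change" fixed point does not hold for
the moment-matching estimator.

BH adjustment is the standard step-up rule, implemented in-package and
cross-checked against statsmodels. Selection is strict (`adjusted p < α`),
α = 0.01, run separately per omics layer.

## Sparse supervised CCA

The first canonical pair under L2 and L1 constraints with supervision
masks. Implementation notes:

- Budget mapping `c = max(1, penalty·√dim)` follows the convention of the
  established sparse-CCA software; `penalty = 1` makes the L1 constraint
  vacuous (Cauchy–Schwarz), so the iteration reduces to the leading
  singular pair of XᵀY — pinned by test at 1e-6.
- v is initialized from the leading right singular vector of the
  supervision-restricted XᵀY; each half-update soft-thresholds and
  L2-normalizes, with the threshold found by bisection on the L1 budget
  (tolerance 1e-8, ≤50 steps). Convergence at max|Δ| < 1e-6 or 50
  iterations. The objective uᵀXᵀYv ascends monotonically (asserted to
  float tolerance).
- Supervision defaults to "keep all" (`q_frac = 1`) because pipeline inputs
  are already DE-screened; standalone users can restrict to the top |t|
  quantile.
- Sign convention: the largest-|u| entry is made positive, flipping u and v
  jointly. Only the first pair is computed.

## SPACE (sparse partial correlations)

All p node-wise regressions are fit jointly under
β_j^{(i)} = ρ_ij √(σ^jj/σ^ii), minimizing
½ Σᵢ‖Xᵢ − Σ_{j≠i} β_j^{(i)} X_j‖² + n·λ₁·Σ_{i<j}|ρ_ij| by cyclic
coordinate descent over pairs (exact soft-threshold updates, deterministic
i<j sweep order, convergence at max|Δρ| < 1e-6 or 500 sweeps), alternating
twice with the weight update σ^ii = n/RSSᵢ from unit initialization. Node
weights are uniform. The n-scaling of the penalty puts the interface value
on the scale the original implementation expects, so the quantile rule
λ₁ = Φ⁻¹(1 − α/(2p²))/√n (α = 1, p recomputed from the actual pooled DE
count) can be passed through directly; the convention is pinned by a
closed-form two-node test. Estimates are clipped to [−1, 1]; symmetry is
exact by construction. The per-node-lasso fallback combination rule
ρ̂ = sign(β̂_j^{(i)})·√(β̂_j^{(i)}β̂_i^{(j)}) (discordant signs → 0 with a
warning) is kept as a cross-check estimator.

A calibration fact that matters for interpreting edge counts: the
coordinate update divides the soft threshold by a ≈2n quadratic term, so
the quantile rule's effective detection threshold on the correlation scale
is λ₁/2 ≈ Φ⁻¹(1 − α/(2p²))/(2√n) — about 1.7 null SDs at n = 200. Edge
recall for planted |ρ| = 0.35 structure is essentially perfect, but a
several-percent tail of null pairs enters the network, so precision is
bounded near 0.3 at p = 40 and the edge-recovery F1 plateaus near 0.45.
This matches the reference analysis's own reported edge density (165 edges
among 3160 pairs at n = 43), i.e. it is a property of the published
penalty rule, not of this implementation; F1-style targets above ~0.6 at
these scales are not attainable without a stricter penalty.

## A*-lasso Bayesian network

The DAG is recovered through its topological ordering. States are subsets
Q_s with g = accumulated LassoScore(v | predecessors) and admissible
heuristic h = Σ_{v∉Q_s} LassoScore(v | V∖{v}) (enlarging a candidate set
never increases a lasso score). The per-node solver is the shooting
algorithm on the Gram matrix, objective ‖x_j − Xβ‖² + nλ‖β‖₁ (interface
λ = 0.2), converged to 1e-10 coordinate tolerance; all successors of one
state share a candidate set and are scored in one batched (numba-jitted)
call, memoized by (node, subset). Tie-breaking is deterministic: lower f,
then deeper state, then smaller subset key. Subset deduplication keeps the
smaller g; the frontier is truncated to the best `queue_limit` entries by
the same key whenever it exceeds the limit (truncation after
deduplication). With an unlimited queue the search is exact — verified
against an exhaustive subset DP on 6-node instances — and with
queue_limit = 1 it degenerates to greedy ordering. Edges are materialized
by re-running the lasso for each node on its full predecessor set;
nonzero coefficients define the parent sets, so the output is acyclic by
construction. Node noise is standard Gaussian, hence the standardized-input
requirement (checked at fit time).

Scaling: the subset state space is 2^p, and on data where many features
are near-independent the f-landscape is a plateau of near-equivalent
orderings; measured at p ≈ 76 with queue 3000 the search advances roughly
one ordering depth per ~2000 expansions, projecting to tens of minutes and
several GB of memoized scores. The estimator therefore enforces a default
cap of 25 nodes (override with `allow_large=True`), and the pipeline runs
the A* stage only within that budget, logging a skip otherwise — the
shell `astar` subcommand and `astar_allow_large` config flag expose the
full-scale search for users prepared to wait.

## Pearson baseline and integration

The baseline tests every off-diagonal pair with t = r√((n−2)/(1−r²)) on
n − 2 df, BH-adjusted across the full pooled family of p(p−1)/2 tests,
edges at adjusted p < 0.01. Empirically its edge set blankets the sparse
methods' edges; this superset behavior is reported as a diagnostic, not
asserted, since it is not guaranteed.

Integration keeps the node-induced subgraph of a source network (SPACE or
A*-lasso) on exactly the sparse-CCA-selected features, annotating nodes
with their loadings. "Adding" the CCA result means node annotation, not
extra edges. The operation is idempotent; network comparison treats
directed edges as unordered pairs and reports counts of total, shared, and
shared cross-omics edges plus sign agreement.

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

- **Dependence structure.** Small miRNA–mRNA modules with a known
  precision matrix: within each module a chain through the miRNAs, a chain
  through the mRNAs, and a miRNA→mRNA matching, each edge's implied partial
  correlation set exactly to ±0.35 (negative across omics, emulating
  repression). This topology keeps every node at degree ≤ 3, so the matrix
  is positive definite at unit diagonal with *exact* implied partial
  correlations; denser within-module cliques cannot reach positive
  definiteness at |ρ| = 0.35 without >10% shrinkage of the implied values,
  which is why they are not used. If a user configuration does force
  diagonal inflation, implied correlations distorted beyond 10% are
  rejected rather than silently shrunk.
- **Signal and noise.** Non-module features are independent Gaussians
  (SD 0.5); per-feature baselines Uniform(6, 12) on the log scale; planted
  case-only DE shifts with magnitudes Uniform(0.5, 2) and random signs
  (comfortable but not saturating power at n = 43 — the source analysis
  states no effect sizes, so these are synthetic conventions); technical
  replicates add Gaussian noise at variance noise_sd²/4 (technical <
  biological; the ratio is a convention and configurable); outliers replace
  entries by mean ± 4 SD at rate 0.005; missingness is uniform at rate
  0.05.
- **Not emulated:** scanner artifacts, probe-level effects, batch
  structure, intensity-dependent variance, informative missingness, and
  correlated missingness between the two platforms. Passing recovery tests
  on this generator demonstrates correctness of the estimators under their
  own model assumptions, not robustness to real microarray pathologies.
- Group-mean DE shifts enter the pooled covariance, so identifiability
  checks of the planted partial correlations (and the SPACE recovery
  experiment) use null effect sizes or group-centered data; the estimand
  is the conditional dependence structure, not the group shift.

Everything is reproducible bit-for-bit from (config, seed).

## Problem sizes in the shipped tests

Exact-search validation uses 6-node/50-sample instances (100 instances
against the DP oracle); the SPACE oracle uses n = 500, p = 6; null
calibration uses 200 replicates of 1000 features at the 13/30 design;
recovery uses n = 200, p = 40 with 20 planted edges; end-to-end runs use
the full 43-sample design with the feature space at its default scale.
These sizes were chosen so each check has enough resolution to fail
informatively while the whole suite stays interactive.

## Known limitations

- The A*-lasso queue-truncation path is heuristic at scale; only the
  unlimited-queue search carries an optimality guarantee.
- The quantile penalty rule's effective threshold (factor-2 note above)
  makes SPACE edge sets permissive at moderate n; users wanting
  false-positive control should tighten λ₁ or post-filter by magnitude.
- DE effect signs depend on the contrast coding (case − control here);
  only magnitudes are comparable across analyses with unknown coding.
- No background correction, probe summarization, or batch adjustment is
  provided; inputs are assumed to be summarized log intensities.
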