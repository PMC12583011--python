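# Methods

This note records what `rfas` computes, the numerical choices behind it,
and where its behaviour can deviate from other implementations.

## Population model and data generation

A simulated condition is specified by its summary moments, the way
factor-analytic simulation studies usually report them: number of factors
(NF), number of variables (NV), primaries per factor, structure class,
mean primary loading (MP), mean secondary loading (MS), and a single
interfactor correlation ρ applied compound-symmetrically.

`build_loading_matrix` expands a summary into a concrete (Λ, Φ, ψ):

* primary loadings are drawn uniformly on [MP − 0.12, MP + 0.12] and shifted
  additively so their mean equals MP *exactly*;
* small secondary loadings are drawn on [0, 2·MS] with random signs and
  rescaled multiplicatively so the mean |secondary| equals MS exactly;
* "complex" structures additionally give 25% of variables one large
  secondary on ±[0.30, 0.45] (counted inside the MS budget);
* residual variances are ψ = 1 − λᵀΦλ, so the implied matrix
  ΛΦΛᵀ + diag(ψ) is a true correlation matrix (unit diagonal) — this
  identity is asserted in the acceptance tests;
* rows implying ψ < 0.01 (Heywood) are redrawn *row-wise* with the mean
  recentring re-applied, up to 100 attempts. Whole-matrix rejection is not
  used because for complex structures with ρ = .6 at least one row is
  inadmissible with high probability on every draw, so whole-matrix
  rejection essentially never terminates.

Data are multivariate normal via the Cholesky factor of the implied
correlation matrix.

**Generator scope.** Only the summary moments are matched; the exact
population loading matrices behind any particular published study are not
reproducible from summaries alone. Consequences: qualitative outcomes
(factor counts, replicability percentages, approximate survivor counts)
reproduce, but fit-index *verdicts* that sit near a threshold may not. In
particular, spreading small secondaries across **all** variables puts
genuine misfit into the zero-cross-loading validation CFA, which can push
mean CFI below the .95 reporting bar for conditions where a generator with
sparser secondaries would pass. The acceptance checks therefore target the
replicability quantities, not the CFA verdicts.

## Estimation

**ML EFA.** The likelihood is profiled over uniquenesses: for fixed ψ the
conditionally optimal loadings come from the top-k eigenpairs of
Ψ^{-1/2}RΨ^{-1/2}, and the gradient in log-ψ follows from the envelope
theorem, dF/dψ_j = [Σ⁻¹(Σ−R)Σ⁻¹]_{jj}·ψ_j. L-BFGS-B with two starts
(1 − squared multiple correlation, and 0.5) and a uniqueness floor of
0.005 (floored solutions are flagged as Heywood). χ² = (n−1)·F_ML with
df = ((p−k)² − p − k)/2; the independence baseline has
χ²_B = −(n−1)·log|R| with df_B = p(p−1)/2.

**Geomin rotation.** Oblique gradient-projection rotation of the
unrotated solution, minimizing Q = Σᵢ (Πⱼ (λᵢⱼ² + ε))^{1/k} with ε = 0.01,
10 random orthonormal starts, step-halving line search. Columns are
sign-aligned (majority-positive loadings) and, when a reference is given,
matched to it by Tucker congruence via optimal assignment. Rotation leaves
the common part ΛΦΛᵀ — and therefore all fit indices — unchanged.

**Fit indices.** CFI = 1 − max(χ²−df, 0)/max(χ²_B−df_B, χ²−df, 0);
TLI = (χ²_B/df_B − χ²/df)/(χ²_B/df_B − 1) (not capped, so TLI can exceed 1
in well-fitting samples); RMSEA = √(max(χ²−df, 0)/(df·(n−1))); SRMR is the
root mean square of the lower-triangular residual correlations, diagonal
included. Saturated models (df = 0) report CFI = TLI = 1, RMSEA = 0.

**Factor-count rules.** Parallel analysis compares observed correlation
eigenvalues with the 95th percentile of 100 random-normal datasets of the
same shape (floor of one factor). EGA estimates a regularized partial
correlation network over a 100-point log-spaced graphical-lasso path,
selects the penalty by EBIC (γ = 0.5), and counts Walktrap communities
(4-step) of the absolute partial-correlation graph; an empty graph falls
back to one factor with a warning.

**Congeneric CFA.** Direct minimization of the ML discrepancy with
parameters: q free loadings, q log-residuals, and Φ through normalized
Cholesky rows (always positive definite, factor variances fixed at 1).
Gradients are analytic for loadings and residuals and central-difference
for the Φ parameters. df = q(q+1)/2 − 2q − k(k−1)/2. Factors need ≥ 2
indicators (≥ 3 when k = 1); two-indicator factors are identified through
the factor correlations.

## Selection procedures

**FS loop.** Removal precedence within a run: misfit first (worst
residual-mass variable while global fit fails), then rule violations. In
the default *sequential* mode one variable is removed per iteration —
unimportant (smallest |primary|), else complex (largest secondary), else
low-D (smallest D) — in *tandem* mode all flagged variables go at once.
D-score: D = λ_p²/Σλ_s², +∞ with no nonzero secondaries, 0 for an all-zero
row.

*Loop termination.* When a solution leaves factors owning fewer than
`min_vars_per_factor` primaries, the factor count must shrink; but
re-estimating k fresh next iteration would return the same k and loop
forever. A persistent cap is therefore kept: k_cap ← k − (number of
deficient factors), and every later iteration uses
k = min(k_estimate, k_cap). With k = 1 the loop switches to an endgame that
only prunes variables with |loading| < .40 and stops.

**Aggregation.** Aborted runs (estimation failure, < 3 variables left) are
excluded from denominators but reported. The modal factor count breaks
ties toward fewer factors. Variables with rating ≥ `cut` (default .80) form
the final model; if the modal k cannot be identified among the survivors
(a factor would end with < 3 indicators), the validation CFA decrements k
until it can, and reports that separately from the modal k.

**ACO short forms.** Ants draw `items_per_factor` items per pool without
replacement with probability ∝ pheromone × heuristic (the item's
full-sample EFA primary loading, floored at 0.05). Candidates are scored by
the full-data congeneric CFA (score = CFI + TLI − RMSEA) and screened at
CFI/TLI ≥ .90, RMSEA ≤ .08; the iteration best deposits
Δ = max(score, 0.01) after evaporation (keep = 0.85). Two standard
robustness devices are built in: max–min trail bounds
[0.1·τ_max, τ_max] with τ_max = Δ/(1 − keep), preventing selection
probabilities from collapsing to zero, and memetic initialization — the
greedy highest-loading candidate is hill-climbed by best-improvement
single swaps and kept as the incumbent if it screens. Search stops after
`patience` (30) runs without improvement or `max_runs` (150). The final
local search reuses the same single-swap hill climb. Stability analysis
reruns a selector on B subsamples (66%, without replacement) and reports
per-item retention percentages and the mean pairwise Jaccard similarity.

**Stepwise baselines.** With k fixed, repeatedly remove the variable whose
removal maximizes TLI, stopping when TLI reaches a target (default .95) or
when the best improvement falls below δ (default .01), never dropping
below 3 variables per factor.

**Comparison statistics.** Share of variables retained in > 80% of
subsamples uses half-up rounding to whole percent. The two-sample t uses
the pooled variance; Cohen's d uses √((s₁² + s₂²)/2) for equal group sizes.

## Tunables

All defaults live in `AlgorithmSettings`: R = 100 subsamples, 66% training
fraction, cut = .80, primary ≥ .40, secondary ≤ .30, D ≥ 3, screening fit
thresholds CFI/TLI ≥ .90 & SRMR/RMSEA ≤ .10, reporting thresholds
CFI/TLI > .95 & RMSEA/SRMR < .08, sequential removal, parallel analysis,
geomin ε = .01 with 10 rotation starts, ≥ 3 variables per factor, seed 0.
Every CLI manifest records the full settings for reproduction.

## Limitations

* Summary-moment generation cannot reproduce a specific published loading
  matrix; near-threshold CFA verdicts may differ (see above).
* Pearson correlations only; no ordinal/polychoric support, no missing
  data.
* The EGA implementation is a compact reimplementation (graphical lasso +
  EBIC + Walktrap) and can differ from other EGA software in edge cases
  such as near-empty networks.
* ACO is stochastic; even with the max–min bounds and memetic start it can
  return a locally optimal subset on an unlucky seed, which is why the
  planted-optimum acceptance property is asserted over a majority of seeds
  rather than every seed.
* P-values and fit indices assume multivariate normality and treat the
  correlation matrix as if it were a covariance matrix with known unit
  variances, as is conventional for these indices.
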