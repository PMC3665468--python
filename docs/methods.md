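# Methods

This note records the statistical content of `prefrank`: the models and
tests it implements, the conventions and numerical choices behind them, what
the synthetic-data generators do and do not emulate, and known limitations.

## Data model and conventions

A ranking of k items is a vector π with π(i) the rank of item i (1 = most
preferred); the ordering π⁻¹ lists items by rank position. Datasets are
individual (N × k) matrices or aggregated tables of distinct rankings with
frequencies N_i; the two are interchangeable (`rank_agg` / `expand`), and
descriptives computed either way agree exactly. Item labels and ranks are
1-based in all I/O; aggregated CSVs carry the k rank columns plus a trailing
`n` frequency column.

Partially ranked data (a prefix 1..t assigned, the rest unranked) are
completed by mean-rank imputation: every unranked item receives the mean of
the unused ranks {t+1, ..., k}, preserving the total k(k+1)/2. Imputed
(tied) rankings are accepted by the descriptives and MDPREF but rejected by
the pair/marginal matrices, the χ² tests, and all model fitting, which
require strict permutations; this split is deliberate, since the likelihoods
and the test covariance structures are derived for complete rankings only.

The mean rank is reported as a mean, m_j = (1/N) Σᵢ N_i π_i(j), so that its
uniform expectation is (k+1)/2 and it feeds the uniformity statistic
directly. The pair matrix uses the literal indicator P_st = Σᵢ N_i
I[π_i(s) > π_i(t)]; because "ranked higher" is ambiguous under the
rank-number convention (rank 1 is best), `destat(direction="preferred")`
returns the transposed convention. All uses of P in the tests are symmetric
in the two conventions.

## χ² tests

With N judges, under uniformity over S_k the three summary statistics and
degrees of freedom are

- mean rank: (12N / k(k+1)) Σ_j (m_j − (k+1)/2)², df = k − 1;
- pairs: 12N [ Σ_{s>t} (P_st/N − ½)² − (1/(k+1)) Σ_j (m_j − (k+1)/2)² ],
  df = C(k, 2);
- marginals: N(k−1) Σ_{s,t} (M_st/N − 1/k)², df = (k−1)².

The pairs form is algebraically identical to the generalized-inverse
quadratic form N d′ Σ⁺ d, where d is the vector of pair-proportion
deviations and Σ the exact covariance of the C(k,2) pair indicators under a
uniform random permutation (eigenvalues (k+1)/12 on the k−1-dimensional
"score" subspace and 1/12 on its complement). The test suite verifies this
identity to 1e-8 on random tables and checks by simulation that each
statistic's mean matches its df and that type-I error is nominal.

A direct rankings-level χ² against expected counts N/k! is provided but
refuses to run when the expected count per ranking falls below 5, the
sparse regime the summary statistics exist for.

Two datasets are compared by flattening the chosen summary (pairs → C(k,2)
cells, marginals → k² cells, mean rank → item rank-sums) into a 2 × q
contingency table and applying the standard χ² test (no continuity
correction), df = q − 1. Cells empty in both datasets carry no information;
the default drops them with a warning (`zeros="pool"` pools them instead) —
with all 49 marginal cells populated at k = 7 this gives df 48. Simulation
(two samples from one Mallows model) shows rejection rates close to the
nominal 5%.

## Distances

Four right-invariant distances are implemented (`tau`, `rho`, `rho2`,
`foot`). Each has a weighted form with one nonnegative weight per rank
position of the reference ranking π₀: Kendall's τ weights a discordant pair
(i, j) by w_{π₀(i)} w_{π₀(j)}; the Spearman family weights item i's
displacement by w_{π₀(i)}. Weight indexing is by rank position — w₁ belongs
to whatever item π₀ ranks first — matching the product form of the weighted
τ; with w ≡ 1 every weighted form reduces exactly to its unweighted
counterpart. `rho` applies the square root to the whole weighted sum.
Weighted distances between two arbitrary rankings re-expressed against a
common reference are symmetric; in model fitting the reference is always the
modal ranking. All distances return floats.

The Kendall stage decomposition writes T(π, π₀) = Σ_{i=1}^{k−1} Vᵢ, where
Vᵢ ∈ {0..k−i} counts the "mistakes" at stage i (items ranked below the
stage-i item by π₀ but above it by π); it is verified exhaustively against
brute-force Kendall distances at k = 4.

## Models

All fits maximize the multinomial log-likelihood Σᵢ N_i log P(πᵢ) and report
a Pearson goodness-of-fit χ² = Σ over all k! rankings of (Oᵢ−Eᵢ)²/Eᵢ with
df = k! − 1 − (number of continuous parameters). The df convention counts
continuous parameters only (Luce k−1, distance-based 1, ϕ-component k−1,
weighted k, ROL (k−1)(M+1)); the discrete modal ranking is not counted.
Exact enumeration of S_k bounds everything at k ≤ 8 (override at your own
risk via `enum_limit`).

**Luce.** Utilities are optimized on the log scale with the last item (or a
chosen reference) fixed at log V = 1's origin, making the problem strictly
concave; L-BFGS-B with the analytic gradient is run from the origin plus two
random restarts, which must agree — disagreement marks the fit
non-converged. Utilities beyond e¹⁵ trigger a boundary warning (an item
essentially never/always ranked last has a divergent MLE).

**Rank-ordered logit.** The utilities enter as V_nj = exp(β_j0 + Σ_m β_jm
x_nm). The exponential link is required: a linear link can push utilities
negative inside the sequential-choice likelihood, and the exploded-logit
literature uses the log-linear form. Standard errors are
observed-information (central-difference Hessian of the negative
log-likelihood at the MLE); p-values are Wald z. Exactly collinear design
columns are detected by pivoted QR and named in the error.

**Distance-based.** For fixed π₀ the profile problem in λ is concave 1-D and
solved by bounded scalar optimization on [0, 30]; the profile likelihood is
monotone decreasing in the total data distance Σᵢ N_i d(πᵢ, π₀), so the MLE
of π₀ simply minimizes that total — searched exhaustively for k ≤ 6 and by
greedy pairwise-swap local search seeded at the mean-rank ordering for
k = 7, 8. Co-optimal modal rankings are reported as ties. λ at the upper
bound (data concentrated on one ranking) raises a boundary warning. For
Kendall's τ the normalizing constant uses the closed form
C(λ) = Π_{i=1}^{k−1} (1 − e^{−(k−i+1)λ}) / (1 − e^{−λ}); other distances
enumerate, exploiting right invariance (C does not depend on π₀).

**ϕ-component.** P(π) ∝ exp(−Σᵢ λᵢ Vᵢ) with the closed-form constant
C(Λ) = Πᵢ (1 − e^{−(k−i+1)λᵢ}) / (1 − e^{−λᵢ}); the likelihood separates
over stages, so each λᵢ is an independent 1-D problem per candidate π₀.
Equal λᵢ recovers Mallows' model exactly (verified in tests).

**Weighted distance-based.** P(π) = e^{−d_w(π, π₀)} / C(w) with w ≥ 0
box-constrained (L-BFGS-B, bounds [0, 30]); there is no separate λ because
the weights absorb the scale — the fit with w ≡ c equals the unweighted fit
with λ = c. Interpretation: large w_i means strong agreement on who belongs
at rank i of the modal ranking.

Model selection is by largest log-likelihood; nested pairs (Luce ⊂ ROL,
Mallows ⊂ ϕ-component, unweighted ⊂ weighted at the same distance) are
checked in the tests.

## MDPREF

The N × k rank matrix is centered by the overall mean rank (k+1)/2 and
decomposed X = U D V′. Judges get √(N−1) U (they number N and must live on
the U side), items V D/√(N−1), so the full-rank product reconstructs X
exactly; explained variance per dimension is D²ᵢᵢ/Σ D²ⱼⱼ. Signs are fixed
deterministically (the largest-magnitude item loading of each dimension is
made positive); singular-value ties keep input order. Rescaling judge
vectors to the item cloud is a plot-only option — returned coordinates are
never rescaled.

## AHP

Weights are the normalized principal right eigenvector of the reciprocal
comparison matrix, computed by power iteration to 1e-12 (guaranteed by
Perron–Frobenius for positive matrices); λ_max ≥ k always, with equality iff
consistent. Saaty's ratio divides (λ_max − k)/(k − 1) by the random index
RI_k, defined as the same quantity averaged over random reciprocal matrices
with upper-triangle entries uniform on the 17-point Saaty scale
{1/9, ..., 1/2, 1, 2, ..., 9}. A table of RI_k for k = 3..15, simulated with
100000 replicates per k under fixed seeds, ships with the package
(`prefrank.ahp.RI_TABLE`); `ri="simulate"` re-estimates it and `ri=<float>`
overrides it. Koczkodaj's index takes the worst triad s < t < u:
min(|1 − b/(ac)|, |1 − ac/b|) with a = a_st, b = a_su, c = a_tu. Analysis is
per-matrix; multi-judge aggregation is out of scope (apply the function per
judge).

## Label ranking

For a query judge, the n_neighbors nearest training judges (Euclidean
distance on covariates, ties broken by training index) supply rankings to a
Luce fit, and the predicted ranking orders items by decreasing utility.
Degenerate neighborhood fits — common for tiny neighborhoods, where some
item is never beaten — fall back to the neighborhood's mean-rank ordering,
which is also the Luce modal ordering in the degenerate limit; a
single-neighbor neighborhood returns that neighbor's ranking verbatim.
Covariates are not standardized by default (neighborhoods are
scale-dependent and the choice is the caller's); `standardize=True` is
available. Cross-validation uses seeded shuffled folds (remainders spread
over the first folds), charges each held-out judge the Kendall distance
between predicted and observed rankings, penalizes an outright prediction
failure with the maximum distance C(k, 2), and prefers the smallest k on
ties. The default grid is k = 1..20 with 10 folds.

## Synthetic data

The samplers are exact, not approximate: Luce rankings are drawn
sequentially with probabilities proportional to remaining utilities (the
vase process, which is the model's definition), and the distance-family
samplers enumerate the full probability table over S_k and sample by
inverse CDF — valid precisely because k ≤ 8. Every sampler takes its own
seed and never touches global state. The ROL fixture draws standard-normal
covariates (optionally around separated cluster centers) and ranks by
per-judge Luce draws with utilities exp(Xβ).

What the generators emulate: complete rankings of a handful of items (the
k ≈ 7 judged-preference regime), with or without judge covariates, under
each model family at chosen concentration. What they do not emulate: real
data's partial rankings beyond prefix-censoring, tied judgments, covariate
measurement error, judge heterogeneity beyond the modeled covariates
(mixtures/latent classes), or k large enough that enumeration fails. Passing
tests therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to misspecification.

Problem sizes in the test suite and acceptance script (N = 200–3000 judges,
k = 3–5, 2000 Monte-Carlo replicates) were chosen as the smallest scales at
which asymptotic calibration and recovery tolerances are comfortably
observable.

## Numerical choices

- Normalizing constants are computed in log space (`logsumexp`;
  `log(-expm1(-x))` for the closed-form factors, with series-free guards at
  λ < 1e-12).
- Dispersion and weight optimizations are bounded ([0, 30]); hitting a bound
  flags the fit (`boundary_`) rather than erroring.
- Luce/ROL convergence tolerance is 1e-8 on the log-likelihood (ftol 1e-10
  to L-BFGS-B); optimizer restarts are seeded (`random_state`).
- Modal-ranking ties and co-optimal fits are surfaced (`ties_`), never
  silently resolved.
- Predictions from utilities break exact ties by item index (stable sort).
- The two-sample χ² handles empty columns by drop (warned) or pool; a
  degenerate comparison of identical tables short-circuits to statistic 0.

## Limitations

- Everything likelihood-based enumerates S_k: k ≤ 8.
- Top-t partial rankings enter only through mean-rank imputation; there is
  no censored-data likelihood, and tie-aware distances are not implemented.
- The rankings-level uniformity test and the two-sample χ² inherit the usual
  sparse-cell caveats of contingency tests.
- Cayley/Hamming/Ulam distances, MANOVA-style comparisons of three or more
  datasets, Bayesian estimation, and mixture/latent-class models are out of
  scope.
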