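# prefrank

Analysis and modeling of **ranking data** — datasets in which each of N
judges ranks the same k items (1 = most preferred). Such data arise
throughout medical informatics, health economics, psychology and market
research, and call for methods beyond ordinary categorical statistics:
rankings live on the permutation group S_k, not on a product of independent
scales.

`prefrank` provides, in one package:

- **Descriptive statistics** — mean rank vector *m*, pair matrix
  *P* (P_st = # judges with π(s) > π(t)), and marginal matrix
  *M* (M_st = # judges ranking item s in position t), with aggregation of raw
  rankings into distinct-ranking/frequency tables and mean-rank imputation of
  partially ranked items.
- **χ² inference** — uniformity tests based on mean ranks, pairs, or
  marginals (asymptotically χ² with k−1, C(k,2), and (k−1)² df), a direct
  rankings-level test when N/k! permits, and a two-sample comparison of
  ranking datasets via a 2×q contingency χ².
- **Rank distances** — Kendall's τ, Spearman's ρ and ρ², and the footrule,
  all right-invariant, plus weighted generalizations with a weight per rank
  position of a reference ranking, and the Kendall stage decomposition
  T(π, π₀) = Σᵢ Vᵢ.
- **Probability models with maximum-likelihood fitting** —
  - *Luce model*: P(π) = Π_j V_{π⁻¹(j)} / Σ_{i≥j} V_{π⁻¹(i)};
  - *rank-ordered logit*: Luce utilities log-linear in judge covariates,
    with observed-information standard errors and Wald p-values;
  - *distance-based model*: P(π) = e^{−λ d(π, π₀)} / C(λ) (Mallows' ϕ-model
    for Kendall's τ, with closed-form C(λ));
  - *ϕ-component model*: one dispersion λᵢ per Kendall stage, closed-form
    C(Λ);
  - *weighted distance-based model*: P(π) = e^{−d_w(π, π₀)} / C(w), the
    rank-position weights absorbing the dispersion;
  - Pearson-residual goodness of fit χ² = Σᵢ (Oᵢ−Eᵢ)²/Eᵢ over all k!
    rankings and log-likelihood model selection.
- **MDPREF** — SVD preference maps: the centered rank matrix X = U D V′
  plotted with judges as vectors (√(N−1) U) and items as points
  (V D/√(N−1)), with per-dimension explained variance.
- **AHP** — principal-eigenvector weights from a reciprocal pairwise
  comparison matrix, Saaty's consistency ratio (with a bundled simulated
  random-index table, k = 3..15) and Koczkodaj's worst-triad index.
- **Label ranking** — local k-nearest-neighbor prediction of a new judge's
  ranking from covariates, with seeded 10-fold cross-validation of the
  neighborhood size (total Kendall distance criterion).
- **Exact samplers** for every model family (sequential "vase" sampling for
  Luce, enumeration inverse-CDF for the distance families), the basis of all
  simulation tests.

Model classes follow the scikit-learn estimator convention (`fit`,
fitted attributes with trailing underscores, `get_params`/`set_params`);
everything is also reachable through plain functions and a `prefrank` CLI.

## Worked example

```python
import numpy as np
from prefrank import (sample_dbm, rank_agg, destat, test_uniform_mean_rank,
                      DistanceBasedModel, WeightedDistanceModel, LuceModel,
                      select_model)

rankings = sample_dbm(pi0=[2, 1, 3, 4], lam=0.8, n=500, dtype="tau", seed=42)
table = rank_agg(rankings)
print("mean rank:", np.round(destat(table).mean_rank, 3))
r = test_uniform_mean_rank(table)
print(f"uniformity (mean rank): chi2 = {r.statistic:.2f}, df = {r.df}, p = {r.p_value:.3g}")

fits = [LuceModel().fit(table),
        DistanceBasedModel("tau").fit(table),
        WeightedDistanceModel("foot").fit(table)]
for f in fits:
    res = f.result()
    print(f"{res.family:12s} loglik = {res.loglik:9.2f}  "
          f"GOF chi2 = {res.gof_chi2:6.1f} (df {res.gof_df})")
best = select_model(fits)
print("selected:", best.family, "| modal ranking:", best.pi0,
      "| lambda =", round(best.params["lambda"], 3))
```

prints

```
mean rank: [2.186 1.608 2.882 3.324]
uniformity (mean rank): chi2 = 515.75, df = 3, p = 1.84e-111
luce         loglik =  -1310.24  GOF chi2 =   75.7 (df 20)
dbm(tau)     loglik =  -1299.40  GOF chi2 =   37.5 (df 22)
wdbm(foot)   loglik =  -1311.31  GOF chi2 =   64.2 (df 19)
selected: dbm(tau) | modal ranking: [2 1 3 4] | lambda = 0.806
```

The mean ranks identify item 2 as most preferred; uniformity is rejected
overwhelmingly; among the candidate models the Mallows ϕ-model attains the
largest log-likelihood and recovers the generating modal ranking
(2, 1, 3, 4) and dispersion (λ̂ = 0.81 vs true 0.8).

The same analyses run from the shell:

```sh
prefrank simulate dbm --params params.json --n 500 --seed 42 --out r.csv
prefrank destat r.csv --mode individual
prefrank test uniform r.csv --mode individual --basis mean_rank
prefrank fit dbm r.csv --mode individual --dtype tau --json
```

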