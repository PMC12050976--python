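# ziqsir

Association tests between a **zero-inflated non-negative outcome** and
covariates of interest, with adjustment covariates, built for settings —
microbiome abundance being the motivating one — where the outcome has a
point mass at zero, is overdispersed, and relates to covariates
**nonlinearly**.

## The model and the test

Write `Y ≥ 0` for the outcome, `Z` (p columns) for the covariates under
test and `C` (q columns) for adjustment covariates. The conditional law of
`Y` is decomposed into two parts:

1. **Presence part** — logistic regression
   `logit P(Y > 0 | X) = Z'η + C'γ`, tested by the likelihood-ratio test of
   `η = 0` (p-value `p_L`).
2. **Positive part** — a single-index quantile model
   `Q_Y(τ | X, Y > 0) = G_τ(Z'α_τ + C'β_τ)` with an *unknown* link `G_τ`,
   approximated by a normalized cubic B-spline sieve `B(u)'θ`. Under the
   null `α_τ = 0`, the index direction is estimated on the unit sphere by
   minimizing the profiled check-loss, and a **rank-score statistic**

   `T_τ = n {τ(1−τ)}⁻¹ ŝ*' (Ω̂₁₁ − Ω̂₁₂ Ω̂₂₂⁺ Ω̂₂₁)⁺ ŝ*`

   is formed from the empirical score
   `ŝ = n⁻¹ Σ {τ − 1(Y_i < Ĝ_τ)} Ĝ'_τ(u_i) X̂_i 1(Y_i>0)`, where `X̂` are the
   covariates residualized against spline functions of the fitted index
   and `ŝ*` is the effective (nuisance-orthogonalized) tested-block score
   (see `docs/methods.md`). Under the null `T_τ → χ²_p`.

3. **Combination** — p-values at quantile levels `τ ∈ {0.1, 0.25, 0.5,
   0.75, 0.9}` and the presence p-value are merged by the weighted Cauchy
   combination
   `T_C = r̂ tan{(0.5−p_L)π} + (1−r̂) Σ_s w_s tan{(0.5−p_τs)π}`,
   with `r̂` the observed zero proportion and central-heavy weights `w_s`;
   `p_combined = 0.5 − arctan(T_C)/π`.

For small samples the χ²-calibration of `T_τ` is unreliable; a fast
permutation scheme recalibrates it: the null fit depends only on `(Y, C)`
and is computed once, rows of `Z` are permuted jointly, and only the
score/statistic (and the logistic LRT) are recomputed per permutation.

## Worked example

```python
import numpy as np
from ziqsir import DGPConfig, gen_dataset, ziqsir_test

sim = gen_dataset(DGPConfig(setting=1, n=500, seed=3))   # built-in DGP
data = sim.to_dataset(test_coords=(1,))                  # test x1, adjust x2..x5
res = ziqsir_test(data.Y, data.Z, data.C, mode="permutation",
                  n_permutations=199, seed=1)
print(f"zero fraction  {res.r_hat:.3f}")
print(f"p_logistic     {res.p_logistic:.4f}")
print("p per tau      ", np.round(res.p_quantile, 4))
print(f"p_combined     {res.p_combined:.4f}")
```

Output:

```
zero fraction  0.336
p_logistic     0.0321
p per tau       [0.2414 0.5091 0.0631 0.1781 0.1406]
p_combined     0.0618
```

`x1` affects both parts of this generating process: the presence-model
LRT is individually significant (0.032), the quantile levels carry
weaker evidence, and the combined p-value lands just above 0.05 for this
particular n=500 draw — at these settings the test rejects in roughly
half of replicates (see the experiment harness below).

Batch use on a count table (features × samples TSV) from the shell:

```sh
ziqsir test --features features.tsv --covariates cov.tsv \
    --test-cols bmi --adjust-cols age,sex --mode auto --seed 1 --out results.tsv
ziqsir simulate --setting 2 --n 500 --seed 7 \
    --covariates-out cov.tsv --response-out y.tsv
ziqsir experiment --kind power --setting 1 --predictors "1;3" \
    --replicates 200 --out power.tsv
```

`ziqsir test` filters features with ≥ 80 % zeros, jitters positive counts
with U(0,1) noise, appends library size as an adjustment covariate,
dummy-codes categorical covariates, and reports per-feature component
p-values, the combined p-value and Benjamini–Hochberg q-values.

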