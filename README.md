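# tskcca — two-stage kernel CCA for sparse nonlinear association discovery

`tskcca` finds **nonlinear associations between two paired multivariate
datasets** — e.g. gene expression vs. metabolite concentrations measured on
the same samples — while selecting the few features (or feature pairs) that
carry each association. Classical CCA sees only linear relations; plain
kernel CCA captures nonlinear ones but cannot discard irrelevant features and
yields a single entangled component. The two-stage approach does both:

1. **Stage 1 — sparse multiple kernel learning on HSIC.** Each view is
   expanded into Gaussian sub-kernels, one per feature
   (`K_x^(m)[n,n'] = exp{-γ (x_nm - x_n'm)^2}`) and optionally one per
   unordered feature pair, each normalized to unit variance in its RKHS.
   Dependence between every cross-view sub-kernel pair is measured by the
   empirical Hilbert–Schmidt Independence Criterion,
   `M[m,l] = Tr(K_x^(m) H K_z^(l) H) / (N-1)²` with `H = I - 11ᵀ/N`.
   The dependence of the combined kernels `K_x = Σ η_m K_x^(m)`,
   `K_z = Σ μ_l K_z^(l)` is then the bilinear form `ηᵀ M μ`, which is
   maximized under `η, μ ≥ 0`, `‖η‖₂ = ‖μ‖₂ = 1`, `‖η‖₁ ≤ c₁`, `‖μ‖₁ ≤ c₂`
   — a penalized matrix decomposition solved by alternating soft-thresholded
   power iterations with rank-1 deflation for successive components.
2. **Stage 2 — regularized kernel CCA.** For each sparse singular pair
   (η⁽ⁱ⁾, μ⁽ⁱ⁾), dual coefficients maximize `αᵀ K_x K_z β` subject to
   `αᵀ(K_x + Nκ/2·I)²α = βᵀ(K_z + Nκ/2·I)²β = 1` (default κ = 0.02), giving
   one canonical component per pair, with train and held-out correlations.

Component significance and the sparsity budgets (c₁, c₂) are judged by a
**permutation test**: the sample order of one view is shuffled B times, the
whole pipeline re-runs on each shuffle, and the observed training canonical
correlation is ranked among the nulls (`p = (1 + #{null ≥ obs}) / (B + 1)`).

## Worked example

Simulate the single-quadratic-association benchmark (z.1 = x.1² + noise
hidden among 9 + 9 pure-noise features — invisible to linear CCA), tune the
budget by permutation, and fit three components:

```bash
tskcca simulate --dataset 1 --n 100 --d 10 --s 0.05 --n-test 100 --seed 7 --out-prefix ds1
tskcca fit --x ds1_X.csv --z ds1_Z.csv --x-test ds1_X_test.csv --z-test ds1_Z_test.csv \
           --tie-budgets --b-grid 100 --components 3 --b 199 --seed 7 --out result.json
# selected c1=1 c2=1; first component rho_train=0.8526 support ['x.1', 'z.1']
tskcca evaluate --result result.json --truth ds1_truth.json
# retrieved=['x.1', 'z.1']
# precision=1.0000 recall=1.0000
```

The result JSON holds, per component, the sparse kernel weights, the
singular value of the HSIC matrix, and the correlations:

| i | nonzero η | nonzero μ | ρ_train | p (B=199) | ρ_test |
|---|-----------|-----------|---------|-----------|--------|
| 1 | x.1: 1.0  | z.1: 1.0  | 0.8526  | 0.005     | 0.8668 |
| 2 | x.4: 1.0  | z.8: 1.0  | 0.1531  | 0.205     | 0.0628 |
| 3 | x.6: 1.0  | z.8: 1.0  | 0.0181  | 0.885     | −0.1717 |

Only the first component is significant, and its support is exactly the
planted pair: the quadratic link is recovered out of sample (ρ_test = 0.87)
even though the linear correlation between x.1 and z.1 is ≈ 0.

The same machinery is available as a library (`tskcca.run_tskcca`,
`tskcca.grid_search`, `tskcca.permutation_test`, ...), and
`--mode feature+pair` adds pair-wise sub-kernels so that multiplicative
interactions such as z.1 = x.1·x.2 become detectable.

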