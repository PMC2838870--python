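# Methods

## Model and procedure

`diffnet` compares gene association networks constructed from two
expression matrices `X₁ (N₁ × p)` and `X₂ (N₂ × p)` over the same `p`
genes. Nothing about the two conditions is modelled parametrically; the
analysis is built from three layers:

1. **Connectivity scores.** Every pair of genes gets a symmetric score
   `s_ik` computed from centered and scaled expression columns
   (standardization uses the `n−1` sample standard deviation). The score
   family is a user choice; the diagonal is never used by any statistic.
2. **Modules.** Given a threshold `ε > 0` and minimum size `m ≥ 1`, the
   genes are connected wherever `|s_ik| ≥ ε` (magnitude, because
   correlation-type scores are signed; the boundary `|s| = ε` counts as
   connected — a measure-zero convention for continuous data). Modules
   are the connected components with at least `m` vertices. Maximality is
   automatic for components, so no separate maximality pass exists, and
   modules are necessarily disjoint — the test suite carries this proof
   obligation as an oracle comparison against brute-force transitive
   closure.
3. **Permutation tests.** The three statistics (non-overlap, class MDA,
   single-gene MDA) are recomputed on `P` random relabellings of the
   pooled `N₁ + N₂` samples. Permutations are sampled uniformly **with
   replacement** from the symmetric group (the identity is not excluded)
   by a seeded PCG64 generator; each permuted group is re-standardized
   before scoring, since the scores are defined on standardized columns.
   The p-value is `#(perm stat ≥ observed)/P`, ties counting as ≥ and the
   observed value not added to the null set, so `p = 0` is possible and is
   rendered as "< 1/P" in text output. Per-gene p-values of the
   single-gene test all come from the same `P` permutations.

Under exchangeability of samples between the conditions this scheme has
the correct size; the suite verifies 5% size for all three tests over 200
null replicates.

### Choices where the design was open

* **Non-overlap summand.** For a gene `g` in modules `F₁(g)`, `F₂(g)`,
  the contribution is `1 − (|F₁∩F₂| − 1)/(|F₁∪F₂| − 1)`. Both defining
  endpoints hold: identical modules give 0, and modules sharing only `g`
  give 1 (forced, since `g` always lies in both of its modules, the
  intersection is never empty). The degenerate case `F₁ = F₂ = {g}`
  (possible only with `m = 1`) contributes 0, reading both-singletons as
  identical structure. The statistic is the mean over all genes in
  modules in both networks, 0 when that set is empty.
* **MDA normalization.** Both `Δ(F)` and `d(g)` are means over their pair
  sets rather than plain sums; this affects only the scale of the
  statistic, not the permutation p-value, and makes values comparable
  across class sizes.
* **PLS pairwise score.** The raw association `T_ik` is the coefficient
  of gene `k` in the `v`-component PLS1 fit of gene `i` on all other
  genes, mapped back to the original (deflation-free) predictors through
  the rotation `W(PᵀW)⁻¹`; the reported score is `(T_ik + T_ki)/2`. The
  symmetrization is isolated in one function so alternative weightings
  are pluggable. Default `v = 3`, user-selectable, capped at
  `min(N−1, p−1)`.
* **Shrinkage intensity.** For partial correlations with fewer samples
  than genes, the correlation matrix is shrunk toward the identity
  (zero-correlation) target with the analytic variance-ratio intensity
  `λ* = Σ_{i<k} Var̂(r_ik) / Σ_{i<k} r_ik²`, clipped to `[0, 1]`, with
  `Var̂(r_ik)` the empirical variance of the products of standardized
  observations (`n/(n−1)³ · Σ_s (w_sik − w̄_ik)²`). Pure noise drives
  `λ*` to 1, large well-correlated samples drive it to 0.
* **Standardization scope.** Each network is standardized separately
  (also inside every permutation split), not jointly across conditions.

## Tunable parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `score_kind` | connectivity score family | `correlation` | `pls` costs `p` PLS fits per score matrix |
| `v` | PLS components | 3 | capped at `min(N−1, p−1)`; early stop when `‖Xᵀy‖ < 1e−12` |
| `shrink`, `shrinkage_lambda` | partial-correlation regularization | off / `"auto"` | required when `N ≤ p` |
| `epsilon` | edge threshold on `|s|` | 0.5 | too large → no modules, too small → one giant module |
| `m` | minimum module size | 5 | raising it removes modules without changing survivors |
| `n_permutations` | permutation count `P` | 1000 | p-values live on the grid `{0, 1/P, …, 1}` |
| `alpha` | significance level | 0.05 | declaration is strict `p < α`; BH declaration uses adjusted `p < α` |

## Synthetic data

`simulate_gaussian_pair` draws the benchmark design: control samples iid
`N(0, I_p)`; treatment samples `N(0, Σ)` where `Σ` has unit diagonal and
off-diagonals `±ρ` among the first `n_important` genes (default 10), the
sign positive when the 1-based index sum is even. The important block is
`(1−ρ)I + ρvvᵀ` with `v_i = (−1)^i`, hence positive definite for all
`ρ ∈ (0,1)` (eigenvalues `1 + (k−1)ρ` and `1 − ρ`). Sampling goes through
the Cholesky factor of `Σ` applied to standard-normal draws from a seeded
generator, so a design plus seed reproduces bit for bit. Index parity is
deliberately 1-based; an off-by-one would flip every sign (harmless to the
magnitude-based tests, fatal to the sign-checking tests).

`simulate_modular_pair` draws block-exchangeable Gaussians in which the
two networks carry different module partitions (default: five 10-gene
modules vs one 50-gene module), a desk-scale stand-in for contrasting
regulatory topologies; it exercises the modular-structure test, whose
power and calibration are checked on it directly.

What the generators do **not** emulate: kinetic (Michaelis–Menten/Hill)
regulatory dynamics, non-Gaussian marginals, heavy tails, measurement
noise structure of microarrays, or batch effects. Passing tests on these
generators therefore demonstrate correctness and calibration of the
statistics under clean exchangeable sampling, not robustness to real
expression data pathologies.

## Monte-Carlo evaluation harness

`run_power_study` repeats: simulate a pair, run the single-gene test,
declare at raw and BH-adjusted `p < α`, and score sensitivity,
specificity, TDR and TNR against the designed important set. Replicate
rates with empty denominators (e.g. TDR when nothing is declared) are
excluded from the average. Per-replicate seeds are spawned from the
master seed via `numpy.random.SeedSequence.spawn`, recorded in the
provenance sidecar, so studies are bit-reproducible. The acceptance
script runs 400 replicates at `p = 20`, 600 at `p = 100` and 100 for the
class test, with `P = 1000` permutations each — scaled-down Monte-Carlo
versions of the reference 1000-replicate design, chosen to keep each study
in the minutes range on a single CPU while holding the Monte-Carlo
standard error of every reported rate near 0.01.

BH-adjusted declarations interact with p-value granularity: the smallest
nonzero p-value is `1/P`, and the BH step multiplies by `p/rank`, so at
`P = 1000` and `p = 100` genes only genes whose observed statistic exceeds
every permutation replicate can be BH-significant unless many genes are
small simultaneously. Adjusted rates therefore depend on `P` more
strongly than raw rates; the harness default `P = 1000` matches the
reference design.

## Numerical notes and degenerate inputs

* A constant gene cannot be standardized and raises a zero-variance error
  naming the gene; the z-score filter instead excludes such genes with a
  warning (its slope standard error is undefined). Near-constant columns
  are detected with a relative tolerance (`sd ≤ 1e−12 · scale`).
* Unshrunk partial correlations require an invertible correlation matrix;
  singular or ill-conditioned input (reciprocal condition number below
  1e−12, or `N ≤ p`) raises an error recommending shrinkage.
* PLS stops early when the weight vector `Xᵀy` is numerically zero
  (`< 1e−12`) and records the effective component count — permutation
  resamples can produce degenerate responses, which must not abort a
  test; a fully degenerate response yields a zero score row plus a
  warning.
* Score matrices are symmetrized exactly (`(S + Sᵀ)/2`) and validated to
  1e−10; correlation-type entries are clipped to `[−1, 1]` against
  rounding.
* Module output order is by smallest contained gene index, for
  deterministic serialization.

## Known limitations

* The permutation scheme assumes exchangeable samples under the null;
  grouped or paired designs are not supported.
* The modular-structure test is conservative when modules rarely form
  (the statistic has an atom at 0, ties inflate the p-value); its
  calibration check uses settings where modules exist with high
  probability.
* Dependence-aware error-rate control beyond BH is out of scope, as are
  mutual-information and Bayesian posterior scores and overlapping-module
  definitions.
* With `P` permutations, p-values below `1/P` are indistinguishable from
  0; choose `P` accordingly for small target levels.
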