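# Methods

This note documents the statistical model behind `gsrank`, the
numerical choices made in implementing it, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## Estimand and statistics

The estimand is the nonparametric relative effect
`p = P(X1 < X2) + ½P(X1 = X2) = ∫F1 dF2`, written with *normalised*
CDFs `F = ½(F⁻ + F⁺)` so that ties are handled without continuity
assumptions.  At analysis `k` it is estimated from mean midranks,
`p̂(k) = (R̄₂ − R̄₁)/N_k + ½`, which is algebraically identical to the
pairwise count `(n₁n₂)⁻¹ ΣΣ c(X₂ⱼ, X₁ᵢ)` with the 0/½/1 kernel.  All
estimators are functions of midranks only and hence invariant under
strictly increasing transformations of the pooled data; ordinal
categories enter as integer codes 1..5, and any order-preserving
coding is equivalent.

Three standardizations of `p̂ − ½` (or of `ψ̂ = logit p̂`) are provided,
differing only in their information (inverse variance):

* WMW: `Î = N n₁ n₂ / σ̂²_R` with the pooled rank variance
  `σ̂²_R = (N−1)⁻¹ Σ (R − (N+1)/2)²`.  Valid as a test of `F1 = F2`;
  under ties-free data `Î = 12 n₁ n₂/(N+1)` exactly.
* BM: `Î = (σ̂₁²/n₁ + σ̂₂²/n₂)⁻¹` with
  `σ̂_g² = (n_h² (n_g−1))⁻¹ Σᵢ (R_gi − R_gi^(g) − R̄_g + (n_g+1)/2)²`,
  the rank form of `V{F_h(X_g)}`.  Valid for the Behrens-Fisher
  hypothesis `p = ½` with arbitrary `F1 ≠ F2`.  A Satterthwaite-Welch
  t-approximation with
  `ν̂ = (σ̂₁²/n₁+σ̂₂²/n₂)² / [σ̂₁⁴/(n₁²(n₁−1)) + σ̂₂⁴/(n₂²(n₂−1))]`
  is available for the repeated p-values (`ν̂ = 2(n−1)` in the
  symmetric case).
* LWO: `ψ̂ = logit p̂` with delta-method information
  `{p̂(1−p̂)}² Î_BM`.

In every case `Z = (effect − null)·√Î`.  The three sequences follow
the canonical joint distribution asymptotically — multivariate normal,
`E(Z_k) = θ√I_k`, `Corr(Z_i, Z_j) = √(I_i/I_j)` for `i ≤ j` — which is
the single structural fact the whole package leans on.

## Error spending and boundaries

Spending functions (one-sided level `α`, default 0.025):

* O'Brien-Fleming type: `f(t) = min{2 − 2Φ(z₁₋α/₂ / √t), α}`
* Pocock type: `f(t) = min[α ln{1 + (e−1)t}, α]`

Information fractions are `τ_k = Î_k / I_max` with a prespecified
`I_max`, capped at 1; `Î_k` is frozen at the analysis where it is
first computed.  Increments are `π₁ = f(τ₁)`,
`π_k = f(τ_k) − f(τ_{k−1})`, and the final analysis always spends the
full remainder `π_K = α − f(τ_{K−1})`, whether or not `Î_K` reached
`I_max`.  No futility boundaries are constructed.

Critical values solve
`P(Z₁ < c₁, …, Z_{k−1} < c_{k−1}, Z_k ≥ c_k) = π_k` recursively under
the canonical correlation `√(τ_i/τ_j)`.  Because that correlation
makes the score process `S_k = Z_k √τ_k` Markov with independent
normal increments, every such probability is a one-dimensional
recursive integral.  It is computed with Gauss-Legendre quadrature —
512 nodes spanning 8.5 standard deviations, density carried stage to
stage — and per-stage root finding by Brent's method (`xtol 1e-10`).
This is fully deterministic (no Monte-Carlo multivariate-normal
calls); total crossing probabilities are reproduced to better than
1e-7, and against an independent multivariate-normal oracle the
recursion agrees to the oracle's own accuracy (~1e-5).  Degenerate
increments (`π_k ≈ 0`) yield `c_k = +∞` (the stage cannot reject);
tied information fractions are separated by 1e-8 before solving.

## Repeated p-values, monitoring and confidence intervals

The repeated p-value is `p_k = 1 − Φ(Ẑ_k)` (or `1 − F_ν̂(Ẑ_k)` for the
BM t-variant, which uses the *same* stage levels and changes only the
p-value computation).  Rejection at stage `k` occurs when
`p_k ≤ α_k = 1 − Φ(c_k)`; the trial then stops.

The 95% repeated confidence intervals are the symmetric two-sided
inversion of the same machinery: with a one-sided 2.5% test, each tail
spends `f` at level 0.025 and the per-tail critical values coincide
with the test's `c_k` (opposite-tail crossings are ignored — their
probability is negligible at these levels).  On the `p` scale the BM
interval is `p̂ ± c_k/√Î_BM` truncated to [0, 1]; the t-variant maps
the normal quantile through `t_ν̂`; the LWO interval is
`ψ̂ ± c_k/√Î_LWO` inverse-logit transformed, hence always inside
(0, 1).  WMW is not inverted (its information is a null quantity, so
the inversion has no `p ≠ ½` interpretation).

A coverage property worth knowing, measured by this package's own
simulation engine at the ordinal study alternative (p = 0.6,
N = (142, 284)): the LWO repeated interval attains ≥ 95% simultaneous
coverage, while the untransformed BM intervals (normal or t) inherit
the BM statistic's finite-sample liberality and sit slightly below
nominal at this sample size.  The acceptance suite asserts the LWO
variant for this reason.

## Power approximation and sample size

For planning, both arm distributions and a constant allocation
`t = n₁ₖ/N_k` are specified; then all true informations are analytic.
`σ₁² = V{F₂(X₁)}` and `σ₂² = V{F₁(X₂)}` give
`I_k^BM = (σ₁²/n₁ₖ + σ₂²/n₂ₖ)⁻¹` and
`I_k^LWO = {p(1−p)}² I_k^BM`; the WMW information uses the mixture
`F = tF1 + (1−t)F2` of the pooled data under `H0` via
`σ²_R(N) = N{(N−2)∫F²dF − (N−3)/4} − (N/4)∫(F⁺−F⁻)dF`
(for continuous mixtures this reduces exactly to `N(N+1)/12`; for
discrete models `∫F²dF = Σ m(x)F(x)²` and the jump term is the sum of
squared atom masses, both exact finite sums).

With critical values `c_k` solved from the spending function under the
respective statistic's true information fractions, the approximate
power against `H1: p > ½` is `1 − Φ_R(a₁, …, a_K)` where `Φ_R` is the
K-variate normal CDF with correlation `√(N_i/N_j)` and

* WMW: `a_k = √(I_k^BM/I_k^WMW)·c_k − √I_k^BM·(p − ½)`
* BM: `a_k = c_k − √I_k^BM·(p − ½)`
* LWO: `a_k = c_k − √I_k^LWO·ψ`

The WMW shift uses the BM information because under the alternative
the variance of `p̂` is the Behrens-Fisher one; the WMW information
only standardizes the boundary.  `Φ_R` is evaluated by the same
Markov recursion as the boundaries (the `N`-fraction correlation is
canonical too).  For `K = 1` the formulas collapse to the familiar
fixed-sample normal approximation, verified to 1e-6.

Sample-size search minimizes `N_K` over multiples of the smallest step
that keeps every per-stage arm size integral (4 for two equal stages
at 1:1; 6 at 2:1), by bracketing and binary search on the monotone
power curve.  Stage fractions default to equal spacing.

Continuous-model integrals (normal arms) use adaptive quadrature with
absolute tolerance 1e-12; discrete models are exact.  Power values are
reproducible to ~1e-6, comfortably inside the 5e-4 agreement the
acceptance suite demands.

## Simulation engine

Each replicate draws its full-trial data once and reveals it
cumulatively by stage; all requested tests are evaluated on the same
data.  `I_max` is the *true* information at the maximum sample size,
computed from the known generating model.  Midranks for all
replicates of a stage are computed in one axis-vectorized call; for
`K ≤ 2` the per-replicate stage levels are solved with a vectorized
bivariate-normal CDF (48-node Gauss-Legendre in arcsine form, absolute
error < 1e-9), using monotonicity to avoid per-replicate root finding
except for the t-variant, which bisects 50 steps for the explicit
`c₂`.  `K ≥ 3` falls back to a per-replicate loop over the scalar
boundary machinery — correct but slower, so large grids at `K ≥ 3`
should budget accordingly.

Seeding is counter-based: the block starting at replicate `r` of
scenario `s` uses `default_rng([base_seed, s, r])`, so any block is
independently reproducible and results are deterministic given the
base seed.

Finite-sample breakdowns are counted per event type and resolved by a
default policy (the exact rules are this package's own choice):

* zero variance estimate → the stage cannot reject; information is
  carried forward unchanged;
* estimated information decreasing between analyses → the information
  fraction is clamped to just above the previous stage's for spending
  purposes, while the statistic keeps the raw estimate;
* `p̂ ∈ {0, 1}` (log win odds undefined) → the BM repeated p-value is
  substituted; in practice this coincides with a zero BM variance
  (complete separation), so the stage resolves as non-rejecting.

At the sample sizes of the study designs these events are vanishingly
rare (none observed in 100,000 replications at N = 284); they occur
routinely only in toy configurations with a dominant category and a
handful of subjects per arm.

## Synthetic data generator

Two model families mirror the simulation study conditions: normal
arms `N(μ_g, σ_g²)`, and 5-category ordinal arms from a latent
`Beta(α_g, β_g)` variable cut at the equidistant grid `0.2k` —
`P(C_k) = B(0.2k) − B(0.2(k−1))`.  The study alternative
`Beta(0.6974797, 1)` vs `Beta(3, 3)` has true `p = 0.6` (to at least
four decimals), which is the configuration the acceptance targets use:
two equally spaced stages, one-sided α = 0.025, 1:1 or 2:1 allocation,
Pocock or O'Brien-Fleming spending, 100,000 replications for the
simulated rejection rates and 10,000-replication smoke versions in the
test suite.  An `empirical_pmf` family accepts arbitrary category
probabilities.

What the generator does *not* emulate: covariates and stratification,
staggered or informative accrual (arrival stage is deterministic, not
a random entry time), dropout and missingness, censored or hierarchical
composite endpoints, and more than two arms.  Passing tests therefore
demonstrate correctness of the sequential rank machinery under clean
iid sampling, not robustness to those real-data features.

## Known limitations

* No futility/binding lower boundaries, adaptive sample-size
  re-estimation or conditional power.
* Power is defined for `p > ½` only (swap arms for the mirror case);
  allocation `t` is an input, not optimized.
* The WMW statistic is only calibrated under `F1 = F2`; under
  heteroskedastic alternatives with unequal allocation its type-I
  error can be badly off — that is a property of the test, faithfully
  reproduced, not a bug.
* Exact/permutation versions of the tests and covariate adjustment
  are out of scope.
* `K ≥ 3` simulation uses the slow per-replicate path.
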