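# gsrank

Group sequential rank tests for the Mann-Whitney parameter.

`gsrank` plans, monitors and simulates two-arm clinical trials whose
primary analysis is based on the **nonparametric relative effect**

    p = P(X1 < X2) + 1/2 P(X1 = X2),

the probability that an observation from arm 2 exceeds one from arm 1,
with ties split evenly (also called the probabilistic index or
Mann-Whitney parameter; `p/(1-p)` are the *win odds*).  It targets
trials with ordinal or skewed endpoints — EDSS-type disability scores,
symptom scales, category counts — where means are not meaningful and
interim analyses are planned, and is aimed at trial statisticians and
methodologists.

Three standardized statistics are supported at each interim analysis
`k` with cumulative arm sizes `n_1k`, `n_2k`, `N_k = n_1k + n_2k`:

* **Wilcoxon-Mann-Whitney (WMW)** — tests `H0: F1 = F2` using the
  pooled-rank variance:
  `Z_k = (p̂(k) - 1/2) √Î_k`, `Î_k = N_k n_1k n_2k / σ̂²_Rk`;
* **Brunner-Munzel (BM)** — tests the nonparametric Behrens-Fisher
  hypothesis `H0: p = 1/2` without assuming equal distributions:
  `Î_k = (σ̂²_1k/n_1k + σ̂²_2k/n_2k)^-1`, optionally with a
  Satterthwaite-Welch t-approximation for the repeated p-values;
* **log win odds (LWO)** — the logit-transformed effect
  `ψ = ln{p/(1-p)}` with delta-method information
  `Î_k = {p̂(1-p̂)}² Î_k^BM`, a variance-stabilized BM variant.

All three sequences asymptotically follow the *canonical joint
distribution* (`E(Z_k) = θ√I_k`, `Corr(Z_i, Z_j) = √(I_i/I_j)`), so
type-I error is controlled by Lan-DeMets error spending (O'Brien-
Fleming-type or Pocock-type), rejection at stage `k` occurring when the
repeated p-value `p_k = 1 - Φ(Ẑ_k)` falls at or below the stage level
`α_k`.  Inverting the BM/LWO boundaries yields repeated confidence
intervals valid simultaneously across all interim looks, and
closed-form multivariate-normal power approximations drive sample-size
search.

## Worked example

Plan a two-stage trial (one interim at half the data, one-sided
α = 0.025, Pocock-type spending, 1:1 allocation) for a 5-category
ordinal endpoint whose arms are modelled by cutting latent
Beta(0.6974797, 1) and Beta(3, 3) variables at the grid 0.2·(0..5) —
a configuration with true relative effect p = 0.6:

```sh
$ gsrank samplesize --method wmw --spending pocock --t 0.5 \
      --target-power 0.80 --model beta-ordinal:0.6974797,1,3,3
method  spending  t    stage_totals  arm1_sizes  arm2_sizes  achieved_power      target_power  step
wmw     pocock    0.5  [142, 284]    [71, 142]   [71, 142]   0.8038205881353224  0.8           4
```

142 patients at the interim and 284 at the final analysis give 80.4%
power.  The analytic power of that design, and the stage levels it
spends, are:

```sh
$ gsrank power --method wmw --spending pocock --t 0.5 --stages 142 284 \
      --model beta-ordinal:0.6974797,1,3,3
method  spending  t    stage_totals  power
wmw     pocock    0.5  [142, 284]    0.8038205881353224

$ gsrank design --k 2 --spending pocock
stage  info_fraction  spent                 stage_level          crit_value
1      0.5            0.015502862673956938  0.01550286267395695  2.156999218344682
2      1.0            0.009497137326043063  0.01386882722536333  2.200976967157774
```

i.e. the interim analysis rejects when the repeated p-value is at or
below 1.55% (Z ≥ 2.157), the final analysis at 1.39% (Z ≥ 2.201); the
two stages together spend the full 2.5%.  `gsrank monitor` applies
such a design to observed data (long-format table with `arm`, `value`,
`stage` columns) and reports per-stage estimates, repeated p-values,
rejection decisions and 95% repeated confidence intervals;
`gsrank simulate` estimates rejection rates by Monte-Carlo.  Every
command is a thin wrapper over the importable library
(`gsrank.power`, `gsrank.monitor`, `gsrank.run_scenario`, ...).

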