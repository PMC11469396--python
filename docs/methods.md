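# Methods

This note records the scientific and numerical choices behind `mixrisk`:
what each stage assumes, which parameters matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Pipeline model

The pipeline chains five stages per simulated individual:

1. **External exposure** `C_ext` (µg/m³) per chemical, drawn from a
   truncated normal `N(mean, sd)` restricted to `[0, ∞)` using each
   region's exposure table. Exposure is sampled *per individual*, not fixed
   per region, so that exposure participates in sensitivity analysis on the
   same footing as the physiological inputs.
2. **Internal dose** `D = C_ext · IR · time · 10⁻³` (mg/kg/day). `time`
   defaults to 1 day because the downstream plasma concentration is a
   steady-state quantity; the 10⁻³ factor converts µg to mg. The inhalation
   rate `IR` (m³/day/kg, already normalized by body weight) is drawn from a
   truncated normal per age bracket.
3. **IVIVE** `C_invitro = D · Css` (µM), where `Css` (µM per mg/kg/day) is
   bootstrap-resampled from a per-stratum sample vector. Strata are age
   group × weight status; the default age brackets
   {[0,17], [18,44], [45,64], [65,100]} follow common toxicokinetic
   population-simulation strata and are configurable. Weight status is
   binary (Normal vs Obese); overweight is collapsed into Normal.
4. **Concentration-response**: the Hill model
   `E(c) = tp / (1 + (ga/c)^gw)`, with `E(0) = 0`. The 2-parameter variant
   fixes `gw = 1`.
5. **Mixture metrics**: GCA and IA responses and their hazard quotients,
   per individual, per assay. One population draw per region is reused
   across all assays, so the same simulated person is evaluated on every
   assay and multi-assay summaries are over a common population.

## Hill fitting

Maximum likelihood over working parameters
`(tp, log10 ga, log gw [3-parameter only], log σ)` with residuals
`resp − E(conc)` under a normal error model by default; a Student-t with
4 df is available as a robust alternative common in high-throughput
screening curve fitting. Responses are fitted on the linear scale;
concentrations are stored linear (µM) and log-transformed only inside the
optimizer.

Numerical choices:

- Bounds: `tp ∈ (0, 1.5·max resp]`, `log10 ga ∈ [min log10 conc − 2,
  max log10 conc + 2]`, `gw ∈ [0.3, 8]`, `σ ∈ (0, 2·sd resp]` — standard
  HTS practice: the top cannot wildly exceed the observed range, the AC50
  must be near the tested window, slopes outside [0.3, 8] are biologically
  implausible.
- L-BFGS-B from a data-driven start (max response, median log
  concentration, `gw = 1`, response SD) plus four deterministically
  jittered restarts; the best of five is reported. Non-convergence returns
  the best point with `converged = False`, never an exception.
- Zero-concentration rows (vehicle controls) enter the likelihood with
  predicted response 0.
- Standard errors from a central-difference Hessian of the negative
  log-likelihood at the optimum, inverted; `se_gw` is delta-method
  transformed from the `log gw` scale. A non-invertible Hessian yields NaN
  standard errors without failing the fit.
- Degenerate inputs (e.g. all-zero responses) are handled by clipping the
  starting top to the bound; the fit may legitimately end at the lower
  `tp` bound.
- Hit-call status is an upstream data attribute (an optional boolean `hit`
  column); non-hit chemical × assay groups are excluded from fitting and
  mixtures rather than re-tested here, since hit-calls originate from the
  curated assay source.

The suite verifies every fitted likelihood against an independent dense
grid search (50³ points over the same bounds, σ profiled analytically), so
the optimizer can never silently underperform an exhaustive baseline.

## GCA, IA, and the hazard quotient

GCA solves `Σ_j C_j / f_j⁻¹(E) = 1`. For slope-1 curves the inverse is
extended linearly through the top, `f⁻¹(E) = ga·E/(tp−E)`, which is
negative for `E > tp` — the device that makes concentration addition
well-defined for partial agonists — and gives the closed form
`E = (Σ tp C/ga)/(1 + Σ C/ga)`. For `gw ≠ 1` the extension would require
fractional powers of negative numbers, so those chemicals use the
restricted inverse `ga·(E/(tp−E))^(1/gw)` and the solve is numeric on
`E ∈ (0, cap)`, where `cap` is the smallest top among restricted
chemicals. The objective is strictly decreasing in `E`, so the root (via
Brent's method, bracketing plus inverse quadratic steps — same guarantee
as bisection under monotonicity, faster) is unique; a solution pinned at
the bracket top is reported with a `bracket_limited` flag rather than an
error. This restriction is the reason 2-parameter (slope-1) fits are the
default feed for mixture work.

A consequence worth stating: GCA is **not** monotone in every component.
With the slope-1 closed form, `∂E/∂C_j ∝ (tp_j − E)`, so raising the dose
of a partial agonist whose top lies below the current mixture response
*dilutes* the mixture. This is classical concentration-addition
pharmacology, and the tests assert it rather than a blanket monotonicity.

IA uses `E = Emax(1 − Π(1 − E_j/Emax))` with `Emax = max_j tp_j` by
default (configurable to a fixed assay ceiling such as 100%): with that
default, the strongest chemical saturates the product and the infinite-dose
IA limit is exactly `Emax`.

The hazard quotient interprets "fraction-of-maximal benchmark" as follows:
hold the individual's mixture proportions `w = C/ΣC` fixed; let `E_lim` be
the mixture response as total dose → ∞ under the chosen model (closed form
for slope-1 GCA; evaluated at a dose 10¹² × the largest AC50 otherwise;
`Emax` for IA); the benchmark `EC_frac` solves
`response(s·w) = fraction · E_lim` by monotone root-finding on `log s`;
`HQ = ΣC / EC_frac`. This definition is self-consistent (HQ = 1 exactly at
the benchmark dose, HQ scales linearly in total dose) — whether such
benchmarks should instead use an absolute activity level or a sum of
per-chemical EC10s is a genuine convention choice, so `fraction` is
exposed in configuration and the definition is documented here. An
unbracketable benchmark (possible only for pathological mixtures) returns
NaN with a warning, never an exception.

## Population simulators

- **Age**: bin sampled proportionally to census-style counts, then uniform
  on the integer ages within the bin.
- **Obesity**: the reported crude prevalence carries survey uncertainty; a
  per-individual prevalence is drawn from `N(prev, (ci_hi−ci_lo)/3.92)`
  truncated to [0, 100] (3.92 = 2·1.96 converts a 95% CI width to a
  standard deviation), then status is Bernoulli.
- **Inhalation rate / exposure**: truncated normals at 0, sampled with
  scipy's `truncnorm` (inverse-CDF based, exact under a seeded generator);
  `sd = 0` degenerates to the constant mean.
- **Css**: uniform resampling with replacement from the stratum's sample
  vector — the bootstrap that lets a tractable number of toxicokinetic
  simulations (≤ ~1000) serve an arbitrarily large simulated population.

All randomness flows through named streams derived from
`(master seed, CRC-32 of stream label)`, so the full pipeline is
bit-reproducible and adding draws to one stage never shifts another's.

## Sensitivity analysis

One-at-a-time: the chosen quantity keeps its full sampling distribution
while every other stage is pinned to a central value — exposure at its
mean, age at the region's median simulated age, obesity at the majority
status, inhalation rate at its bracket mean, Css at its stratum median
(median, not mean, because bootstrap Css pools are right-skewed), and Hill
parameters at their point estimates. A varied age propagates
*deterministically* downstream (the bracket mean and stratum median of the
varied age), so age variation reaches the output without re-randomizing
the other stages. `fit_params` varies by sampling `(tp, log10 ga)` from
`Normal(estimate, SE)` independently per draw; parameter covariance is
ignored — a documented simplification. The all-fixed baseline is exactly
constant within a region, and a varied parameter changes the output if and
only if its input distribution is non-degenerate.

## Summaries

Empirical quantiles use type-7 (linear interpolation of order statistics,
numpy's default), fixed so the implementation and the brute-force test
oracle agree bitwise. Multi-assay summaries compute, per region, the
`summary_p` quantile over assays of each assay's `assay_q` quantile over
individuals; non-finite per-individual values (NaN hazard quotients from
unbracketable benchmarks) are excluded before quantile computation.

## Synthetic data

The generator emits every input the pipeline reads, schema-valid by
construction: unit-square region grids; per-region exposure means drawn
uniform on [0.1, 2] µg/m³ with a 30% coefficient of variation (the range of
typical annual-average single-pollutant air-toxics concentrations);
young-heavy age pyramids of 10 000 persons per region; obesity prevalences
in 25–45% with ±3-point CIs (typical of county-level surveillance);
inhalation rates declining from 0.35 (children) to 0.18 (over-65)
m³/day/kg; lognormal Css pools (meanlog uniform on [0, 1.5], sdlog 0.5,
200 samples per stratum) with modest obesity and age offsets; and Hill
curves with `tp ∈ [50, 120]`, `log10 ga ∈ [−1, 1]`, `gw ∈ [0.8, 2]`
observed at 11 log-spaced concentrations (10⁻³–10² µM) × 3 replicates with
σ = 3% activity noise. The default sizes — 10 regions, 7 chemicals,
1 assay, with a 20-assay variant for multi-assay summaries — mirror the
shape of a state-wide single-assay analysis at desk scale.

What the fixtures do *not* emulate: spatial correlation of exposures
between neighboring regions, correlation between chemicals, assay-to-assay
correlation, or realistic chemical-specific toxicokinetics. Passing tests
therefore demonstrate the correctness of the computational chain and its
statistical contracts, not predictive validity on real exposure data.

Problem sizes used by the verification script (`scripts/acceptance.py`):
1000 random mixtures for the GCA oracle, 100 curves for the fit-recovery
study, 40 000 draws per simulator check, 200 assays × 20 regions for the
quantile-of-quantiles oracle, and 10 regions × 100 individuals for the
end-to-end determinism run — sizes at which the Monte Carlo error bounds
quoted in the tests are comfortably resolvable on a single CPU.

## Known limitations

- GCA with heterogeneous non-unit slopes has no extended inverse; the
  restricted bracket caps the response at the weakest restricted top and
  flags bracket-limited solutions.
- The Hill inverse is ill-conditioned where `E` approaches `tp` (relative
  error amplified by `tp/(tp−E)`); round-trip identities are only
  meaningful while `(tp−E)/tp` exceeds ~10⁻⁶ in float64.
- Standard errors ignore parameter covariance in sensitivity perturbation.
- Serialization round-trips are lossless for float64 via 17-significant-
  digit CSV and round-trip float parsing; GeoJSON properties round-trip to
  better than 10⁻⁹.
- No geospatial exposure modeling: regions and exposures are inputs, and
  the only geometry operations are validity checks and choropleth export.
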