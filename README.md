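# mixrisk

Source-to-outcome chemical mixture risk mapping in Python.

`mixrisk` is for environmental health scientists and risk assessors who want
to connect georeferenced external chemical exposures (e.g. annual-average
hazardous air pollutants by county) to population-level estimates of
biological effect measured by high-throughput in-vitro screening assays. The
pipeline simulates a population per region (age, obesity status, inhalation
rate), converts external air concentrations to internal doses and then to
in-vitro-equivalent tissue concentrations (IVIVE via steady-state plasma
concentration factors), fits Hill concentration-response curves to assay
data, computes per-individual mixture responses and hazard quotients, and
summarizes risk by region — including a multi-assay "quantile of assay-level
quantiles" summary — with built-in one-at-a-time sensitivity analysis, plots,
and choropleth exports. A synthetic-data generator replaces all external
data dependencies, so the whole workflow is runnable and testable offline.

## The models

**Hill concentration-response.** For each chemical × assay, the response at
concentration *c* (µM) is

    E(c) = tp / (1 + (ga / c)^gw)

with top `tp` (% activity), AC50 `ga` (µM), and Hill coefficient `gw`
(fixed to 1 in the 2-parameter model). Parameters are fitted by maximum
likelihood (normal or Student-t(4) residuals) over
`(tp, log10 ga, log gw, log σ)` with bounded quasi-Newton from multiple
starts; standard errors come from the inverse observed information.

**Dosimetry.** Internal dose and in-vitro-equivalent concentration per
individual *i* and chemical *j*:

    D_ij = C_ext,ij · IR_i · time · 10⁻³        [mg/kg/day]
    C_invitro,ij = D_ij · Css_ij                [µM]

where `IR` is inhalation rate (m³/day/kg) and `Css` the steady-state plasma
concentration per unit dose rate (µM per mg/kg/day), bootstrap-resampled
from per-stratum (age group × weight status) toxicokinetic sample vectors.

**Mixture response.** Two classical models:

- *Generalized concentration addition (GCA)*: solve `Σ_j C_j / f_j⁻¹(E) = 1`
  with inverse dose-response functions extended to partial agonists
  (`f⁻¹(E) = ga·E/(tp−E)` for slope-1 curves). All-slope-1 mixtures have the
  closed form `E = (Σ tp_j C_j/ga_j) / (1 + Σ C_j/ga_j)`; others are solved
  numerically on a restricted bracket.
- *Independent action (IA)*: `E = Emax · (1 − Π_j (1 − E_j/Emax))`.

**Hazard quotient.** Holding mixture proportions fixed, `EC_frac` is the
total concentration whose mixture response reaches a fraction (default 10%)
of the limiting (infinite-dose) mixture response; `HQ = ΣC / EC_frac`, so
HQ = 1 exactly at the benchmark and HQ scales linearly with dose.

**Summaries.** Regional risk is an empirical quantile (type-7) of a
per-individual metric (`GCA.Eff`, `IA.Eff`, `GCA.HQ`, `IA.HQ`); multi-assay
risk is the *p*-quantile over assays of each assay's *q*-quantile over
individuals.

## Worked example

```python
from mixrisk import Config, load_inputs, run_pipeline
from mixrisk.fixtures import FixtureSpec, write_fixture_dir
from mixrisk.summarize import summarize_region, region_summary_frame

write_fixture_dir(FixtureSpec(seed=42, n_regions=4, n_chemicals=3), "inputs")
cfg = Config(seed=42, n_per_region=200, n_hill_params=2)
state = run_pipeline(load_inputs("inputs", cfg))
print(state.summary())
```

```
4 regions, 200 simulated individuals per region
chemicals: 3   assays: 1
  exposure     present [12 rows]
  age          present [16 rows]
  obesity      present [4 rows]
  ir           present [4 rows]
  css          present [4800 rows]
  concresp     present [99 rows]
  hill_params  present [3 fits]
  population   present [4 regions]
  responses    present [4 region x assay]
  sensitivity  absent
```

```python
s = summarize_region(state.responses, "GCA.Eff", [0.5])
print(region_summary_frame(s).to_string(index=False))
```

```
region_id    assay  metric  prob    value
   SYN001 ASSAY001 GCA.Eff   0.5 0.053913
   SYN002 ASSAY001 GCA.Eff   0.5 0.092372
   SYN003 ASSAY001 GCA.Eff   0.5 0.024999
   SYN004 ASSAY001 GCA.Eff   0.5 0.024594
```

The median GCA mixture response in region SYN002 is 0.092% activity — the
typical simulated resident's combined exposure to the three chemicals
drives this assay to about a tenth of a percent of its activity scale, far
below the fitted curve tops (50–120%): low predicted risk, with region-level
contrast (SYN002 ≈ 3.7× SYN004) coming from the exposure and population
tables. Median hazard quotients in the same run are 0.003–0.012, i.e. total
mixture concentrations are 100–300× below the 10%-response benchmark dose.

The same workflow from the shell:

```sh
mixrisk fixtures --seed 42 --n-regions 4 --n-chemicals 3 --out inputs
mixrisk run config.yaml --out results      # config.yaml points input_dir at inputs/
mixrisk plot results/state --type hill --out plots
mixrisk sensitivity results/state --out sensitivity.csv
```

`run` writes the serialized state, regional and multi-assay summary CSVs, a
result GeoJSON (one property per metric-quantile per region, ready for
choropleth mapping), and a run manifest with the seed and config echo.

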