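"""Regional and multi-assay risk summarization, and one-at-a-time sensitivity.

Assay-level summaries are empirical quantiles (type-7, linear interpolation
of order statistics) of a per-individual metric within a region x assay.
Multi-assay risk is the "p total quantile of the q assay-level quantiles":
for each region, take each assay's q-quantile over individuals, then the
p-quantile of that per-assay vector.

Sensitivity analysis reruns the per-individual metric with exactly one input
quantity stochastic while everything else is pinned to a central value:
exposure at its mean, age at the region's median simulated age, obesity at
the majority status, inhalation rate at its bracket mean, Css at its stratum
median, and Hill parameters at their point estimates.  Varying
``fit_params`` instead samples (tp, log10_ga) from Normal(estimate, SE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import population_sim
from .datamodel import Config, HillParams, PipelineState, PopulationDraw
from .mixture import calc_internal_dose, calc_invitro_concentration, calc_response
from .rng import RNGHandle

__all__ = ["RegionSummary", "MultiAssaySummary", "summarize_region",
           "summarize_multi_assay", "compute_sensitivity",
           "SENSITIVITY_PARAMS"]

log = logging.getLogger(__name__)

SENSITIVITY_PARAMS = ("age", "obesity", "inhalation_rate", "css",
                      "exposure", "fit_params")


@dataclass
class RegionSummary:
    """Quantiles of one metric for one region x assay."""

    region_id: str
    assay: str
    metric: str
    quantiles: dict  # prob -> value

    def __post_init__(self):
        probs = sorted(self.quantiles)
        vals = [self.quantiles[p] for p in probs]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("quantile values must be non-decreasing in prob")


@dataclass
class MultiAssaySummary:
    """p-quantile over assays of the q assay-level quantiles, one region."""

    region_id: str
    metric: str
    assay_q: float
    summary_p: float
    value: float


def _quantile(x, p):
    # type-7: linear interpolation of order statistics (numpy default)
    return float(np.quantile(np.asarray(x, float), p, method="linear"))


def summarize_region(responses: dict, metric: str, probs) -> list:
    """Empirical quantiles of a per-individual metric, per region x assay.

    ``responses`` maps (region_id, assay) -> MixtureResult.
    """
    out = []
    for (rid, assay), res in sorted(responses.items()):
        vals = res.metric(metric)  # raises on unknown metric
        if vals.size == 0:
            raise ValueError(f"empty results for region {rid}, assay {assay}")
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            raise ValueError(f"no finite {metric} values for region {rid}, "
                             f"assay {assay}")
        out.append(RegionSummary(region_id=rid, assay=assay, metric=metric,
                                 quantiles={float(p): _quantile(finite, p)
                                            for p in probs}))
    return out


def region_summary_frame(summaries) -> pd.DataFrame:
    rows = [{"region_id": s.region_id, "assay": s.assay, "metric": s.metric,
             "prob": p, "value": v}
            for s in summaries for p, v in sorted(s.quantiles.items())]
    return pd.DataFrame(rows)


def summarize_multi_assay(region_summaries, assay_q: float,
                          summary_p: float) -> list:
    """Quantile-of-quantiles multi-assay summary per region."""
    by_region = {}
    for s in region_summaries:
        if assay_q not in s.quantiles:
            raise ValueError(f"assay {s.assay} (region {s.region_id}) has no "
                             f"quantile at prob {assay_q}")
        by_region.setdefault((s.region_id, s.metric), []).append(
            s.quantiles[assay_q])
    return [MultiAssaySummary(region_id=rid, metric=metric,
                              assay_q=float(assay_q), summary_p=float(summary_p),
                              value=_quantile(vals, summary_p))
            for (rid, metric), vals in sorted(by_region.items())]


def multi_assay_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([{"region_id": s.region_id, "metric": s.metric,
                          "assay_q": s.assay_q, "summary_p": s.summary_p,
                          "value": s.value} for s in summaries])


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity

def _central_age(state: PipelineState, rid: str) -> int:
    pop = state.population.get(rid)
    if pop is not None:
        return int(np.median(pop.age))
    # fall back to the count-weighted median of the age table
    bins = state.age[state.age["region_id"] == rid].sort_values("age_lo")
    cum = bins["count"].cumsum()
    row = bins[cum >= cum.iloc[-1] / 2].iloc[0]
    return int((row["age_lo"] + row["age_hi"]) // 2)


def _central_obese(state: PipelineState, rid: str) -> bool:
    pop = state.population.get(rid)
    if pop is not None:
        return bool(np.mean(pop.obese) > 0.5)
    row = state.obesity[state.obesity["region_id"] == rid].iloc[0]
    return bool(row["prev"] > 50.0)


def _ir_bracket_mean(state: PipelineState, ages: np.ndarray) -> np.ndarray:
    out = np.full(len(ages), np.nan)
    for row in state.ir.itertuples(index=False):
        mask = (ages >= row.age_lo) & (ages <= row.age_hi)
        out[mask] = row.ir_mean
    if np.isnan(out).any():
        bad = np.unique(np.asarray(ages)[np.isnan(out)])
        raise ValueError(f"ages outside all inhalation-rate brackets: {bad.tolist()}")
    return out


def _css_stratum_median(state: PipelineState, casrns, ages, obese) -> np.ndarray:
    cfg = state.config
    labels = [population_sim.age_group_label(a, cfg.css_age_groups) for a in ages]
    status = np.where(np.asarray(obese, bool), "Obese", "Normal")
    med = state.css.groupby(["casrn", "age_group", "weight_status"])["css"].median()
    out = np.empty((len(ages), len(casrns)))
    for j, cas in enumerate(casrns):
        for i, (lab, st) in enumerate(zip(labels, status)):
            out[i, j] = med[(cas, lab, st)]
    return out


def _sensitivity_draw(state: PipelineState, rid: str, vary, handle: RNGHandle,
                      n: int) -> PopulationDraw:
    """Population draw with only ``vary`` stochastic; None = all central.

    A varied age propagates deterministically downstream (bracket-mean
    inhalation rate and stratum-median Css of the varied age), so age
    variation reaches the output without re-randomizing the other stages.
    """
    cfg = state.config
    exp = state.exposure[state.exposure["region_id"] == rid].sort_values("casrn")
    casrns = exp["casrn"].tolist()

    if vary == "age":
        bins = state.age[state.age["region_id"] == rid]
        age = population_sim.simulate_age(bins, n, handle.stream(f"sens:age:{rid}"))
    else:
        age = np.full(n, _central_age(state, rid), dtype=int)

    if vary == "obesity":
        row = state.obesity[state.obesity["region_id"] == rid].iloc[0]
        obese = population_sim.simulate_obesity(row["prev"], row["ci_lo"],
                                                row["ci_hi"], n,
                                                handle.stream(f"sens:obesity:{rid}"))
    else:
        obese = np.full(n, _central_obese(state, rid), dtype=bool)

    if vary == "inhalation_rate":
        ir = population_sim.simulate_inhalation_rate(age, state.ir,
                                                     handle.stream(f"sens:ir:{rid}"))
    else:
        ir = _ir_bracket_mean(state, age)

    if vary == "exposure":
        _, c_ext = population_sim.simulate_exposure(exp, n,
                                                    handle.stream(f"sens:exposure:{rid}"))
    else:
        c_ext = np.tile(exp["mean"].to_numpy(float), (n, 1))

    if vary == "css":
        _, css = population_sim.sample_css(state.css, age, obese,
                                           handle.stream(f"sens:css:{rid}"),
                                           groups=cfg.css_age_groups)
    else:
        css = _css_stratum_median(state, casrns, age, obese)

    d_int = calc_internal_dose(c_ext, ir, cfg.time_days, cfg.dose_scaling)
    c_invitro = calc_invitro_concentration(d_int, css)
    return PopulationDraw(region_id=rid, age=age, obese=obese, ir=ir,
                          casrns=casrns, c_ext=c_ext, css=css,
                          d_int=d_int, c_invitro=c_invitro)


def _perturbed_params(hill_params, rng) -> list:
    """Sample (tp, log10_ga) from Normal(estimate, SE); gw, sigma fixed."""
    out = []
    for hp in hill_params:
        se_tp = hp.se_tp if np.isfinite(hp.se_tp) else 0.0
        se_ga = hp.se_log10_ga if np.isfinite(hp.se_log10_ga) else 0.0
        tp = max(rng.normal(hp.tp, se_tp), 1e-6)
        l10ga = rng.normal(hp.log10_ga, se_ga)
        out.append(HillParams(casrn=hp.casrn, assay=hp.assay, tp=tp,
                              log10_ga=l10ga, gw=hp.gw, sigma=hp.sigma,
                              converged=hp.converged, n_params=hp.n_params))
    return out


def compute_sensitivity(state: PipelineState, vary=SENSITIVITY_PARAMS,
                        assay: str | None = None,
                        metric: str | None = None,
                        include_baseline: bool = True) -> dict:
    """One-at-a-time sensitivity of the configured metric.

    Returns a dict mapping parameter name (plus ``"baseline"`` when
    requested) to a long DataFrame (region_id, assay, individual, metric,
    value).  Results are stored on ``state.sensitivity`` as well.
    """
    cfg = state.config
    metric = metric or cfg.metric
    if not state.hill_params:
        raise ValueError("run the pipeline (or fit) before sensitivity analysis")
    by_assay = {}
    for hp in state.hill_params:
        by_assay.setdefault(hp.assay, []).append(hp)
    if assay is None:
        assay = sorted(by_assay)[0]
    if assay not in by_assay:
        raise ValueError(f"unknown assay {assay!r}")
    params = by_assay[assay]

    labels = (("baseline",) if include_baseline else ()) + tuple(vary)
    unknown = set(labels) - set(SENSITIVITY_PARAMS) - {"baseline"}
    if unknown:
        raise ValueError(f"unknown sensitivity parameters: {sorted(unknown)}; "
                         f"expected {SENSITIVITY_PARAMS}")

    handle = RNGHandle(cfg.seed)
    out = {}
    for label in labels:
        draw_vary = None if label in ("baseline", "fit_params") else label
        rows = []
        for region in state.regions:
            rid = region.region_id
            pop = _sensitivity_draw(state, rid, draw_vary, handle, cfg.n_per_region)
            if label == "fit_params":
                rng = handle.stream(f"sens:fit:{rid}")
                vals = np.empty(cfg.n_per_region)
                one = PopulationDraw(region_id=rid, age=pop.age[:1],
                                     obese=pop.obese[:1], ir=pop.ir[:1],
                                     casrns=pop.casrns, c_ext=pop.c_ext[:1],
                                     css=pop.css[:1], d_int=pop.d_int[:1],
                                     c_invitro=pop.c_invitro[:1])
                for i in range(cfg.n_per_region):
                    res = calc_response(one, _perturbed_params(params, rng), cfg)
                    vals[i] = res.metric(metric)[0]
            else:
                res = calc_response(pop, params, cfg)
                vals = res.metric(metric)
            rows.append(pd.DataFrame({
                "region_id": rid, "assay": assay,
                "individual": np.arange(len(vals)),
                "metric": metric, "value": vals}))
        out[label] = pd.concat(rows, ignore_index=True)
    state.sensitivity.update(out)
    return out
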