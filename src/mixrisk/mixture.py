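"""Dosimetry and chemical-mixture response calculators.

The pipeline's calculator stages:

* internal dose from external air concentration and inhalation rate,
  ``d_int = c_ext * ir * time * scaling`` (mg/kg/day);
* in-vitro-equivalent concentration by IVIVE,
  ``c_invitro = d_int * Css`` (uM);
* mixture response of the in-vitro concentrations under two classical
  mixture models — generalized concentration addition (GCA), which solves
  ``sum_i C_i / f_i^{-1}(E) = 1`` with inverse dose-response functions
  extended to partial agonists, and independent action (IA),
  ``E = Emax * (1 - prod_i (1 - f_i(C_i)/Emax))``;
* a hazard quotient (HQ) comparing the mixture's total concentration to the
  benchmark concentration producing a fixed fraction of the limiting
  mixture response at the same proportions (HQ = 1 exactly at benchmark).

For slope-1 (gw = 1) curves GCA has the closed form
``E = (sum tp_i C_i / ga_i) / (1 + sum C_i / ga_i)``; mixtures with non-unit
slopes are solved numerically with the restricted inverse on
``E in (0, min_i tp_i)``, flagging solutions pinned at the bracket edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize

from .datamodel import Config, HillParams, MixtureResult, PopulationDraw
from .dose_response import HillCurve, hill_forward

__all__ = [
    "MixtureInput",
    "calc_internal_dose",
    "calc_invitro_concentration",
    "calc_independent_action",
    "calc_gca",
    "GCAResult",
    "calc_hazard_quotient",
    "calc_response",
]

log = logging.getLogger(__name__)

_GW_UNIT_TOL = 1e-9


@dataclass
class MixtureInput:
    """One individual's in-vitro concentrations and the assay's curves."""

    c_invitro: np.ndarray          # uM per chemical
    curves: Sequence[HillCurve]
    emax: Optional[float] = None   # % activity ceiling for IA

    def __post_init__(self):
        self.c_invitro = np.asarray(self.c_invitro, dtype=float)
        if self.c_invitro.shape != (len(self.curves),):
            raise ValueError("c_invitro and curves must have matching length")
        top = max(c.tp for c in self.curves)
        if self.emax is None:
            self.emax = top
        elif self.emax < top:
            raise ValueError(f"Emax={self.emax} below max tp={top}")


def calc_internal_dose(c_ext, ir, time_days: float = 1.0, scaling: float = 1e-3):
    """Internal dose (mg/kg/day) = c_ext (ug/m3) * ir (m3/day/kg) * time * scaling.

    ``time_days`` defaults to 1 (steady-state plasma assumption);
    ``scaling`` defaults to 1e-3 (ug -> mg).
    """
    c_ext = np.asarray(c_ext, dtype=float)
    ir = np.asarray(ir, dtype=float)
    if np.any(c_ext < 0) or np.any(ir < 0) or time_days < 0 or scaling < 0:
        raise ValueError("all internal-dose inputs must be >= 0")
    if c_ext.ndim == 2 and ir.ndim == 1:
        ir = ir[:, None]
    out = c_ext * ir * time_days * scaling
    return out if out.ndim else float(out)


def calc_invitro_concentration(d_int, css):
    """In-vitro-equivalent concentration (uM) = d_int (mg/kg/day) * Css."""
    d_int = np.asarray(d_int, dtype=float)
    css = np.asarray(css, dtype=float)
    if np.any(d_int < 0) or np.any(css < 0):
        raise ValueError("dose and Css must be >= 0")
    out = d_int * css
    return out if out.ndim else float(out)


def calc_independent_action(mix: MixtureInput) -> float:
    """IA mixture response: Emax * (1 - prod(1 - f_i(C_i)/Emax))."""
    effs = np.array([hill_forward(c, cv) for c, cv in zip(mix.c_invitro, mix.curves)])
    if np.any(effs > mix.emax * (1 + 1e-12)):
        raise ValueError("individual response exceeds Emax")
    return float(mix.emax * (1.0 - np.prod(1.0 - effs / mix.emax)))


class GCAResult(NamedTuple):
    value: float
    bracket_limited: bool


def _gca_closed_form(c, tps, gas) -> float:
    num = np.sum(tps * c / gas)
    den = 1.0 + np.sum(c / gas)
    return float(num / den)


def _gca_numeric(c, tps, gas, gws) -> GCAResult:
    """Solve sum C_i / finv_i(E) = 1 numerically.

    Slope-1 chemicals use the extended inverse ga * E / (tp - E) (its
    reciprocal term (tp - E) / (ga * E) is linear through and beyond E = tp,
    the partial-agonist extension); chemicals with gw != 1 use the restricted
    inverse ga * (E / (tp - E))^(1/gw), which caps the bracket at their
    smallest top.  The objective is strictly decreasing in E, so the root is
    unique; a solution pinned at the bracket top is flagged.
    """
    unit = np.abs(gws - 1.0) < _GW_UNIT_TOL
    cap = float(np.max(tps)) if unit.all() else float(np.min(tps[~unit]))
    lo = cap * 1e-12
    hi = cap * (1.0 - 1e-12)

    def objective(E):
        tot = 0.0
        if unit.any():
            tot += np.sum(c[unit] * (tps[unit] - E) / (gas[unit] * E))
        if (~unit).any():
            finv = gas[~unit] * (E / (tps[~unit] - E)) ** (1.0 / gws[~unit])
            tot += np.sum(c[~unit] / finv)
        return tot - 1.0

    if objective(hi) > 0:
        # even at the top of the bracket the mixture "needs" more response:
        # solution pinned at the weakest restricted chemical's top
        return GCAResult(hi, True)
    # objective -> +inf as E -> 0+ (any positive C), so the root is bracketed
    E = optimize.brentq(objective, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return GCAResult(float(E), False)


def calc_gca(mix: MixtureInput, full: bool = False, solver: str = "auto"):
    """GCA mixture response (% activity).

    Slope-1 mixtures use the closed form with the extended (partial-agonist)
    inverse; mixtures with non-unit slopes are solved numerically
    (``solver="numeric"`` forces that path, e.g. to cross-check the closed
    form).  ``full=True`` returns a :class:`GCAResult` with the
    bracket-limited flag; otherwise a float.
    """
    if solver not in ("auto", "closed", "numeric"):
        raise ValueError(f"unknown solver {solver!r}")
    c = mix.c_invitro
    tps = np.array([cv.tp for cv in mix.curves])
    gas = np.array([cv.ga for cv in mix.curves])
    gws = np.array([cv.gw for cv in mix.curves])
    all_unit = bool(np.all(np.abs(gws - 1.0) < _GW_UNIT_TOL))
    if np.all(c == 0):
        res = GCAResult(0.0, False)
    elif solver == "numeric":
        res = _gca_numeric(c, tps, gas, gws)
    elif all_unit:
        res = GCAResult(_gca_closed_form(c, tps, gas), False)
    elif solver == "closed":
        raise ValueError("closed-form GCA requires all Hill coefficients == 1")
    else:
        res = _gca_numeric(c, tps, gas, gws)
    return res if full else res.value


def _mixture_response(s, w, mix: MixtureInput, method: str) -> float:
    scaled = MixtureInput(s * w, mix.curves, emax=mix.emax)
    if method == "GCA":
        return calc_gca(scaled)
    if method == "IA":
        return calc_independent_action(scaled)
    raise ValueError(f"unknown mixture method {method!r}")


def _limiting_response(w, mix: MixtureInput, method: str) -> float:
    """Mixture response as total dose -> infinity at fixed proportions w."""
    tps = np.array([cv.tp for cv in mix.curves])
    gas = np.array([cv.ga for cv in mix.curves])
    gws = np.array([cv.gw for cv in mix.curves])
    active = w > 0
    if method == "IA":
        return float(mix.emax) if np.any(tps[active] > 0) else 0.0
    if np.all(np.abs(gws[active] - 1.0) < _GW_UNIT_TOL):
        # closed-form limit of the slope-1 GCA formula
        return float(np.sum(tps[active] * w[active] / gas[active])
                     / np.sum(w[active] / gas[active]))
    # GCA response is monotone in total dose at fixed proportions: evaluate
    # at a dose far beyond every AC50 to approximate the saturation limit
    s_big = 1e12 * float(np.max(gas))
    return _mixture_response(s_big, w, mix, "GCA")


def calc_hazard_quotient(mix: MixtureInput, method: str = "GCA",
                         fraction: float = 0.10) -> float:
    """Hazard quotient of the mixture at its current total concentration.

    Holding the mixture proportions fixed, the benchmark concentration
    ``EC_frac`` is the total dose whose mixture response equals
    ``fraction`` of the limiting (infinite-dose) response; then
    ``HQ = total / EC_frac``.  HQ = 1 exactly at the benchmark; doubling
    every concentration doubles HQ.  Returns 0 for a zero mixture and NaN
    (with a warning) if the benchmark cannot be bracketed.
    """
    c = mix.c_invitro
    total = float(np.sum(c))
    if total == 0:
        return 0.0
    w = c / total
    e_lim = _limiting_response(w, mix, method)
    e_star = fraction * e_lim
    lo, hi = 1e-12 * total, 1e12 * total

    def g(log_s):
        return _mixture_response(10.0 ** log_s, w, mix, method) - e_star

    glo, ghi = g(np.log10(lo)), g(np.log10(hi))
    if not (glo < 0 < ghi):
        log.warning("hazard-quotient benchmark not bracketed "
                    "(method=%s, fraction=%g); returning NaN", method, fraction)
        return float("nan")
    log_ec = optimize.brentq(g, np.log10(lo), np.log10(hi),
                             xtol=1e-13, maxiter=200)
    return total / 10.0 ** log_ec


# ---------------------------------------------------------------------------
# population-level driver

def calc_response(population: PopulationDraw, hill_params: Sequence[HillParams],
                  config: Config) -> MixtureResult:
    """Mixture responses (GCA, IA) and hazard quotients for every individual.

    ``hill_params`` is the fit set for a single assay.  Chemicals are joined
    on CASRN between the population's in-vitro concentrations and the fits;
    chemicals lacking a fit are dropped with a warning, an empty intersection
    is an error.
    """
    assays = {hp.assay for hp in hill_params}
    if len(assays) != 1:
        raise ValueError(f"hill_params must cover exactly one assay, got {assays}")
    assay = assays.pop()
    if population.c_invitro is None:
        raise ValueError("population.c_invitro not populated")

    by_cas = {hp.casrn: hp for hp in hill_params}
    keep = [j for j, cas in enumerate(population.casrns) if cas in by_cas]
    dropped = [cas for cas in population.casrns if cas not in by_cas]
    if not keep:
        raise ValueError("no chemicals joinable between population and hill_params")
    if dropped:
        log.warning("assay %s: dropping chemicals without fits: %s", assay, dropped)

    curves = [HillCurve.from_params(by_cas[population.casrns[j]]) for j in keep]
    emax = config.emax if config.emax is not None else max(c.tp for c in curves)
    conc = population.c_invitro[:, keep]

    n = population.n
    gca = np.empty(n)
    ia = np.empty(n)
    gca_hq = np.empty(n)
    ia_hq = np.empty(n)
    for i in range(n):
        mix = MixtureInput(conc[i], curves, emax=emax)
        gca[i] = calc_gca(mix)
        ia[i] = calc_independent_action(mix)
        gca_hq[i] = calc_hazard_quotient(mix, "GCA", config.hq_fraction)
        ia_hq[i] = calc_hazard_quotient(mix, "IA", config.hq_fraction)

    return MixtureResult(region_id=population.region_id, assay=assay,
                         gca_eff=gca, ia_eff=ia, gca_hq=gca_hq, ia_hq=ia_hq,
                         emax=emax)


def responses_frame(responses: dict) -> "pd.DataFrame":
    """Long-format export: region, assay, individual index, metric, value."""
    import pandas as pd
    rows = []
    for (region_id, assay), res in responses.items():
        for metric in ("GCA.Eff", "IA.Eff", "GCA.HQ", "IA.HQ"):
            vals = res.metric(metric)
            rows.append(pd.DataFrame({
                "region_id": region_id, "assay": assay,
                "individual": np.arange(len(vals)),
                "metric": metric, "value": vals,
            }))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["region_id", "assay", "individual", "metric", "value"])
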