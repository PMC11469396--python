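"""Hill concentration-response model: evaluation, inversion, and ML fitting.

The Hill model used throughout is

    E(c) = tp / (1 + (ga / c)^gw)

with top ``tp`` (% activity), AC50 ``ga`` (uM), and Hill coefficient ``gw``.
A 2-parameter fit fixes ``gw = 1``.  Fitting maximizes the likelihood of the
residuals ``resp - E(conc)`` under a normal (default) or Student-t(4) error
model with scale ``sigma``, over the working parameters
``(tp, log10_ga, log gw [if free], log sigma)`` using bounded L-BFGS-B from
multiple starts.  Standard errors come from the inverse observed information
(numerical Hessian at the optimum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datamodel import HillParams

__all__ = ["HillCurve", "hill_forward", "hill_inverse", "fit_hill", "fit_hill_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HillCurve:
    """Hill curve parameters on the linear concentration scale."""

    tp: float   # top, % activity
    ga: float   # AC50, uM
    gw: float = 1.0  # Hill coefficient

    def __post_init__(self):
        if not (self.tp > 0 and self.ga > 0 and self.gw > 0):
            raise ValueError(f"tp, ga, gw must all be > 0, got "
                             f"({self.tp}, {self.ga}, {self.gw})")

    @classmethod
    def from_params(cls, hp: HillParams) -> "HillCurve":
        return cls(tp=hp.tp, ga=hp.ga, gw=hp.gw)


def hill_forward(c, curve: HillCurve):
    """Response at concentration ``c`` (uM); 0 at c = 0, bounded above by tp."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = np.zeros_like(c, dtype=float)
    pos = c > 0
    out[pos] = curve.tp / (1.0 + (curve.ga / c[pos]) ** curve.gw)
    return out if out.ndim else float(out)


def hill_inverse(E, curve: HillCurve, extended: bool = False):
    """Concentration producing response ``E``.

    With ``extended=False`` requires 0 < E < tp and inverts the Hill curve
    exactly.  With ``extended=True`` (slope-1 curves only) uses the linear
    extension ``ga * E / (tp - E)``, which continues through E >= tp with
    negative values — the device that lets concentration addition handle
    partial agonists.
    """
    E = np.asarray(E, dtype=float)
    if extended:
        if curve.gw != 1.0:
            raise ValueError("extended inverse requires gw == 1")
        if np.any(E == curve.tp):
            raise ValueError("extended inverse undefined at E == tp")
        out = curve.ga * E / (curve.tp - E)
    else:
        if np.any(E <= 0) or np.any(E >= curve.tp):
            raise ValueError(f"inverse requires 0 < E < tp={curve.tp}")
        out = curve.ga / ((curve.tp / E) - 1.0) ** (1.0 / curve.gw)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting

def _neg_loglik(theta, conc, resp, free_gw, error_model):
    if free_gw:
        tp, l10ga, lgw, lsig = theta
        gw = np.exp(lgw)
    else:
        tp, l10ga, lsig = theta
        gw = 1.0
    sigma = np.exp(lsig)
    ga = 10.0 ** l10ga
    pred = np.zeros_like(conc)
    pos = conc > 0
    pred[pos] = tp / (1.0 + (ga / conc[pos]) ** gw)
    r = resp - pred
    if error_model == "normal":
        n = r.size
        return 0.5 * n * np.log(2 * np.pi * sigma ** 2) + np.sum(r ** 2) / (2 * sigma ** 2)
    elif error_model == "t4":
        return -np.sum(stats.t.logpdf(r, df=4, scale=sigma))
    raise ValueError(f"unknown error_model {error_model!r}")


def _numerical_hessian(f, x, rel_step=1e-4):
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    # guard non-finite entries (e.g. at a bound)
    if not np.all(np.isfinite(H)):
        return None
    return H


def fit_hill(conc, resp, n_params: int = 3, error_model: str = "normal",
             casrn: str = "", assay: str = "") -> HillParams:
    """Fit a 2- or 3-parameter Hill model by maximum likelihood.

    Parameters
    ----------
    conc, resp : array-like
        Concentrations (uM, >= 0; zeros are vehicle controls predicted at 0)
        and responses (% activity).
    n_params : {2, 3}
        2 fixes the Hill coefficient at 1.
    error_model : {"normal", "t4"}
        Residual distribution; t4 mirrors robust HTS curve fitting.

    Returns
    -------
    HillParams
        Estimates, standard errors from the inverse observed information,
        residual scale, and a convergence flag.  Non-convergence returns the
        best point found with ``converged=False`` — never an exception.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("conc and resp must have the same length")
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    if n_params not in (2, 3):
        raise ValueError("n_params must be 2 or 3")
    n_distinct = np.unique(conc).size
    if n_distinct < n_params + 1:
        raise ValueError(f"need at least {n_params + 1} distinct concentrations, "
                         f"got {n_distinct}")

    free_gw = n_params == 3
    pos = conc[conc > 0]
    logc = np.log10(pos)
    resp_sd = max(float(np.std(resp)), 1e-3)
    max_resp = float(np.max(resp))

    tp_hi = 1.5 * max(max_resp, 1e-3)
    bounds_map = {
        "tp": (1e-6, tp_hi),
        "l10ga": (logc.min() - 2.0, logc.max() + 2.0),
        "lgw": (np.log(0.3), np.log(8.0)),
        "lsig": (np.log(1e-6), np.log(2.0 * resp_sd)),
    }
    names = ["tp", "l10ga", "lgw", "lsig"] if free_gw else ["tp", "l10ga", "lsig"]
    bounds = [bounds_map[nm] for nm in names]

    def clip(x):
        return np.array([np.clip(v, lo, hi) for v, (lo, hi) in zip(x, bounds)])

    base = {"tp": max(max_resp, 1e-3), "l10ga": float(np.median(logc)),
            "lgw": 0.0, "lsig": np.log(resp_sd)}
    x0 = clip(np.array([base[nm] for nm in names]))

    # deterministic jittered restarts
    jrng = np.random.default_rng(12345)
    starts = [x0]
    for _ in range(4):
        jitter = jrng.normal(scale=[0.2 * tp_hi if nm == "tp" else 0.5 for nm in names])
        starts.append(clip(x0 + jitter))

    args = (conc, resp, free_gw, error_model)
    best, best_val, any_success = None, np.inf, False
    for s in starts:
        try:
            res = optimize.minimize(_neg_loglik, s, args=args, method="L-BFGS-B",
                                    bounds=bounds)
        except (ValueError, FloatingPointError):  # pragma: no cover
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best, best_val = res, res.fun
        any_success = any_success or bool(res.success)
    if best is None:
        x = x0
        converged = False
    else:
        x = best.x
        converged = any_success and bool(best.success)

    if free_gw:
        tp, l10ga, lgw, lsig = x
        gw = float(np.exp(lgw))
    else:
        tp, l10ga, lsig = x
        gw = 1.0
    sigma = float(np.exp(lsig))

    # SEs in the reported parametrization (tp, log10_ga, gw); delta method
    # for gw = exp(lgw) via the chain rule on the working Hessian.
    se = {"tp": np.nan, "l10ga": np.nan, "lgw": np.nan}
    H = _numerical_hessian(lambda t: _neg_loglik(t, *args), x)
    if H is not None:
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.all(d[:len(names) - 1] > 0):
                se["tp"] = float(np.sqrt(d[0]))
                se["l10ga"] = float(np.sqrt(d[1]))
                if free_gw:
                    se["lgw"] = float(np.sqrt(d[2])) * gw  # d(gw)/d(lgw) = gw
        except np.linalg.LinAlgError:
            pass

    return HillParams(
        casrn=casrn, assay=assay,
        tp=float(tp), log10_ga=float(l10ga), gw=gw, sigma=sigma,
        se_tp=se["tp"], se_log10_ga=se["l10ga"],
        se_gw=se["lgw"] if free_gw else 0.0,
        converged=converged, n_params=n_params,
    )


def fit_hill_table(concresp, n_params: int = 3, error_model: str = "normal"):
    """Fit every chemical x assay group of a concentration-response table.

    ``concresp`` needs columns casrn, assay, conc, resp; an optional boolean
    ``hit`` column marks upstream hit-calls, and groups whose hit flag is
    false are skipped (their activity is not a significant departure from
    null, so they contribute nothing to mixtures).
    """
    out = []
    for (casrn, assay), g in concresp.groupby(["casrn", "assay"], sort=True):
        if "hit" in g.columns and not bool(g["hit"].iloc[0]):
            log.info("skipping non-hit %s x %s", casrn, assay)
            continue
        out.append(fit_hill(g["conc"].to_numpy(), g["resp"].to_numpy(),
                            n_params=n_params, error_model=error_model,
                            casrn=casrn, assay=assay))
    return out


def hill_params_frame(params) -> "pd.DataFrame":
    """Fitted parameters as one row per chemical x assay."""
    import pandas as pd
    return pd.DataFrame([{
        "casrn": p.casrn, "assay": p.assay, "tp": p.tp,
        "log10_ga": p.log10_ga, "gw": p.gw, "sigma": p.sigma,
        "se_tp": p.se_tp, "se_log10_ga": p.se_log10_ga, "se_gw": p.se_gw,
        "converged": p.converged, "n_params": p.n_params,
    } for p in params])
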