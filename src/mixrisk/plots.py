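"""Plot exports: exposure densities, fitted curves, response densities,
sensitivity densities, and regional choropleths.

All functions write PNG files and return the written paths; styling is
deliberately plain matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from matplotlib.collections import PolyCollection  # noqa: E402

from .datamodel import PipelineState  # noqa: E402
from .dose_response import HillCurve, hill_forward  # noqa: E402

__all__ = ["plot_exposure", "plot_hill", "plot_response", "plot_sensitivity",
           "plot_map", "plot_state"]


def _density(ax, values, label=None, **kw):
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        # degenerate sample: show a spike instead of a KDE
        x = values[0] if values.size else 0.0
        ax.axvline(x, label=label, **kw)
        return
    from scipy.stats import gaussian_kde
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 200)
    ax.plot(grid, kde(grid), label=label, **kw)


def plot_exposure(state: PipelineState, out_dir) -> list:
    """Per-chemical density of simulated external exposure, pooled regions."""
    if not state.population:
        raise ValueError("exposure plot needs a simulated population "
                         "(run the pipeline first)")
    out_dir = Path(out_dir)
    pops = list(state.population.values())
    casrns = pops[0].casrns
    fig, axes = plt.subplots(len(casrns), 1, figsize=(6, 1.8 * len(casrns)),
                             squeeze=False)
    for j, cas in enumerate(casrns):
        ax = axes[j, 0]
        _density(ax, np.concatenate([p.c_ext[:, j] for p in pops]))
        ax.set_ylabel(cas, fontsize=7)
    axes[-1, 0].set_xlabel("external exposure (ug/m3)")
    fig.suptitle("Simulated exposure densities")
    fig.tight_layout()
    path = out_dir / "exposure.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return [path]


def plot_hill(state: PipelineState, out_dir) -> list:
    """Fitted Hill curves over their concentration-response data."""
    if not state.hill_params:
        raise ValueError("hill plot needs fitted parameters (run fit first)")
    out_dir = Path(out_dir)
    params = state.hill_params
    ncol = 3
    nrow = -(-len(params) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow),
                             squeeze=False)
    for k, hp in enumerate(params):
        ax = axes[divmod(k, ncol)]
        if state.concresp is not None:
            g = state.concresp[(state.concresp["casrn"] == hp.casrn)
                               & (state.concresp["assay"] == hp.assay)]
            pos = g[g["conc"] > 0]
            ax.semilogx(pos["conc"], pos["resp"], "k.", ms=3)
        grid = np.logspace(hp.log10_ga - 3, hp.log10_ga + 3, 100)
        ax.semilogx(grid, hill_forward(grid, HillCurve.from_params(hp)), "r-")
        ax.set_title(f"{hp.casrn}\n{hp.assay}", fontsize=6)
    for k in range(len(params), nrow * ncol):
        axes[divmod(k, ncol)].axis("off")
    fig.tight_layout()
    path = out_dir / "hill.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return [path]


def plot_response(state: PipelineState, out_dir, metric: str | None = None) -> list:
    """Metric densities per assay, grouped by obesity status."""
    if not state.responses:
        raise ValueError("response plot needs mixture results "
                         "(run the pipeline first)")
    out_dir = Path(out_dir)
    metric = metric or state.config.metric
    assays = sorted({a for (_, a) in state.responses})
    fig, axes = plt.subplots(len(assays), 1, figsize=(6, 2.2 * len(assays)),
                             squeeze=False)
    for i, assay in enumerate(assays):
        ax = axes[i, 0]
        for status, flag in (("normal", False), ("obese", True)):
            vals = np.concatenate([
                res.metric(metric)[state.population[rid].obese == flag]
                for (rid, a), res in state.responses.items() if a == assay])
            if vals.size:
                _density(ax, vals, label=status)
        ax.set_ylabel(assay, fontsize=7)
        ax.legend(fontsize=7)
    axes[-1, 0].set_xlabel(metric)
    fig.tight_layout()
    path = out_dir / "response.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return [path]


def plot_sensitivity(state: PipelineState, out_dir) -> list:
    """Kernel densities of the metric, one curve per varied parameter."""
    if not state.sensitivity:
        raise ValueError("sensitivity plot needs sensitivity results "
                         "(run compute_sensitivity first)")
    out_dir = Path(out_dir)
    fig, ax = plt.subplots(figsize=(6, 4))
    for param, df in sorted(state.sensitivity.items()):
        _density(ax, df["value"], label=param)
    ax.set_xlabel(df["metric"].iloc[0])
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = out_dir / "sensitivity.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return [path]


def plot_map(state: PipelineState, summaries, out_dir, metric: str,
             prob: float) -> list:
    """Choropleth of a regional metric-quantile over the region polygons."""
    regions = [r for r in state.regions if r.geometry is not None]
    if not regions:
        raise ValueError("map plot needs region geometries")
    values = {s.region_id: s.quantiles[prob] for s in summaries
              if s.metric == metric and prob in s.quantiles}
    missing = [r.region_id for r in regions if r.region_id not in values]
    if missing:
        raise ValueError(f"no {metric} q{prob} summary for regions {missing}")
    polys, vals = [], []
    for r in regions:
        geoms = getattr(r.geometry, "geoms", [r.geometry])
        for geom in geoms:
            polys.append(np.asarray(geom.exterior.coords))
            vals.append(values[r.region_id])
    fig, ax = plt.subplots(figsize=(6, 5))
    coll = PolyCollection(polys, array=np.array(vals), edgecolor="k",
                          cmap="viridis")
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    fig.colorbar(coll, ax=ax, label=f"{metric} q{round(prob * 100)}")
    fig.tight_layout()
    out_dir = Path(out_dir)
    path = out_dir / "map.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return [path]


def plot_state(state: PipelineState, out_dir, types=("exposure", "hill",
                                                     "response")) -> list:
    out = []
    dispatch = {"exposure": plot_exposure, "hill": plot_hill,
                "response": plot_response, "sensitivity": plot_sensitivity}
    for t in types:
        out.extend(dispatch[t](state, out_dir))
    return out
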