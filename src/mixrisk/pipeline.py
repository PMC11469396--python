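"""End-to-end pipeline orchestration.

``run_pipeline`` takes a state holding the input tables, then: fits Hill
curves per chemical x assay (unless fits are already present), simulates the
population per region (age -> obesity -> inhalation rate -> external
exposure -> Css), derives internal doses and in-vitro-equivalent
concentrations, and computes mixture responses per region x assay.  One
population draw per region is reused across all assays, so the same
simulated person is evaluated on every assay.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io_formats, population_sim
from .datamodel import Chemical, Config, PipelineState, PopulationDraw
from .dose_response import fit_hill_table
from .mixture import calc_internal_dose, calc_invitro_concentration, calc_response
from .rng import RNGHandle

__all__ = ["load_inputs", "simulate_population", "run_pipeline"]

log = logging.getLogger(__name__)


def load_inputs(input_dir, config: Config) -> PipelineState:
    """Build a state from a directory of input files (fixture layout)."""
    input_dir = Path(input_dir)
    state = PipelineState(config=config)
    state.regions = io_formats.read_regions(input_dir / "regions.geojson")
    state.exposure = io_formats.read_exposure(input_dir / "exposure.csv")
    state.age = io_formats.read_age(input_dir / "age.csv")
    state.obesity = io_formats.read_obesity(input_dir / "obesity.csv")
    state.ir = io_formats.read_ir(input_dir / "ir.csv")
    state.css = io_formats.read_css(input_dir / "css.csv")
    state.concresp = io_formats.read_concresp(input_dir / "concresp.csv")
    chem_file = input_dir / "chemicals.csv"
    if chem_file.exists():
        import pandas as pd
        state.chemicals = [Chemical(casrn=str(r.casrn), name=str(r.name))
                           for r in pd.read_csv(chem_file).itertuples(index=False)]
    else:
        state.chemicals = [Chemical(casrn=c)
                           for c in sorted(state.exposure["casrn"].unique())]
    return state


def simulate_population(state: PipelineState, region_id: str,
                        handle: RNGHandle) -> PopulationDraw:
    """Draw one region's simulated individuals and all dosimetry stages."""
    cfg = state.config
    n = cfg.n_per_region
    bins = state.age[state.age["region_id"] == region_id]
    if bins.empty:
        raise ValueError(f"no age bins for region {region_id}")
    age = population_sim.simulate_age(bins, n, handle.stream(f"age:{region_id}"))

    ob = state.obesity[state.obesity["region_id"] == region_id]
    if ob.empty:
        raise ValueError(f"no obesity record for region {region_id}")
    row = ob.iloc[0]
    obese = population_sim.simulate_obesity(row["prev"], row["ci_lo"], row["ci_hi"],
                                            n, handle.stream(f"obesity:{region_id}"))

    ir = population_sim.simulate_inhalation_rate(age, state.ir,
                                                 handle.stream(f"ir:{region_id}"))

    exp = state.exposure[state.exposure["region_id"] == region_id]
    if exp.empty:
        raise ValueError(f"no exposure records for region {region_id}")
    casrns, c_ext = population_sim.simulate_exposure(exp, n,
                                                     handle.stream(f"exposure:{region_id}"))

    css_casrns, css = population_sim.sample_css(state.css, age, obese,
                                                handle.stream(f"css:{region_id}"),
                                                groups=cfg.css_age_groups)
    if css_casrns != casrns:
        # restrict both to the common chemical set, sorted-CASRN order
        common = sorted(set(casrns) & set(css_casrns))
        if not common:
            raise ValueError(f"region {region_id}: no chemicals shared between "
                             "exposure and Css tables")
        c_ext = c_ext[:, [casrns.index(c) for c in common]]
        css = css[:, [css_casrns.index(c) for c in common]]
        casrns = common

    d_int = calc_internal_dose(c_ext, ir, cfg.time_days, cfg.dose_scaling)
    c_invitro = calc_invitro_concentration(d_int, css)
    return PopulationDraw(region_id=region_id, age=age, obese=obese, ir=ir,
                          casrns=casrns, c_ext=c_ext, css=css,
                          d_int=d_int, c_invitro=c_invitro)


def run_pipeline(state: PipelineState) -> PipelineState:
    """Fit, simulate, and compute mixture responses for every region x assay."""
    cfg = state.config
    if not state.hill_params:
        if state.concresp is None:
            raise ValueError("state has neither hill_params nor concresp data")
        log.info("fitting Hill models (%d-parameter, %s errors)",
                 cfg.n_hill_params, cfg.error_model)
        state.hill_params = fit_hill_table(state.concresp,
                                           n_params=cfg.n_hill_params,
                                           error_model=cfg.error_model)
    handle = RNGHandle(cfg.seed)
    by_assay = {}
    for hp in state.hill_params:
        by_assay.setdefault(hp.assay, []).append(hp)

    for region in state.regions:
        rid = region.region_id
        log.info("simulating region %s (n=%d)", rid, cfg.n_per_region)
        pop = simulate_population(state, rid, handle)
        state.population[rid] = pop
        for assay in sorted(by_assay):
            state.responses[(rid, assay)] = calc_response(pop, by_assay[assay], cfg)
    state.check_joinable()
    return state
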