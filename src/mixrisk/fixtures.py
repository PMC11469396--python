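"""Synthetic input generation with known ground truth.

Every pipeline input — region polygons, per-region exposure means, binned age
pyramids, obesity prevalences, age-bracketed inhalation rates, per-stratum
Css bootstrap samples, and concentration-response records — can be generated
here, schema-valid by construction and reproducible from a seed.  The
generators emulate the shapes of their real-world counterparts (annual
air-toxics means, census age tables, surveillance prevalence estimates,
exposure-factors inhalation rates, toxicokinetic Css simulations, HTS
concentration-response series) at desk scale; they do not mimic real spatial
correlation.

The default :class:`FixtureSpec` is sized like a single-assay state-wide
analysis (10 regions, 7 chemicals, 1 assay); ``multi_assay_spec`` scales the
assay axis up for quantile-of-quantiles summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry as sgeom

from .datamodel import Chemical, Region
from .dose_response import HillCurve, hill_forward
from .population_sim import DEFAULT_AGE_GROUPS
from .rng import RNGHandle

__all__ = ["FixtureSpec", "multi_assay_spec", "gen_regions", "gen_concresp",
           "gen_population_inputs", "gen_chemicals", "write_fixture_dir"]

# EPA exposure-factors-style inhalation rates (m3/day/kg): highest in
# childhood, declining with age.
_IR_BRACKETS = ((0, 17, 0.35, 0.08), (18, 44, 0.22, 0.05),
                (45, 64, 0.20, 0.05), (65, 100, 0.18, 0.04))

# age-pyramid weights per Css age group (young-heavy, realistic crude shape)
_AGE_WEIGHTS = (0.22, 0.36, 0.26, 0.16)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 0
    n_regions: int = 10
    n_chemicals: int = 7
    n_assays: int = 1
    tp_range: tuple = (50.0, 120.0)           # % activity
    log10_ga_range: tuple = (-1.0, 1.0)       # log10 uM
    gw_range: tuple = (0.8, 2.0)              # Hill coefficient
    noise_sd: float = 3.0                     # concentration-response noise, % activity
    conc_grid: tuple = tuple(np.logspace(-3, 2, 11))  # uM
    n_reps: int = 3
    exposure_mean_range: tuple = (0.1, 2.0)   # ug/m3
    exposure_cv: float = 0.3                  # sd = cv * mean
    obesity_prev_range: tuple = (25.0, 45.0)  # crude %
    obesity_ci_halfwidth: float = 3.0         # %
    region_population: int = 10000            # total age-table count per region
    css_meanlog_range: tuple = (0.0, 1.5)     # log uM per mg/kg/day
    css_sdlog: float = 0.5
    n_css_samples: int = 200                  # bootstrap pool size per stratum
    age_groups: tuple = DEFAULT_AGE_GROUPS

    def __post_init__(self):
        if self.n_regions < 1 or self.n_chemicals < 1 or self.n_assays < 1:
            raise ValueError("n_regions, n_chemicals, n_assays must be >= 1")
        if self.noise_sd < 0 or self.exposure_cv < 0:
            raise ValueError("noise_sd and exposure_cv must be >= 0")


def multi_assay_spec(seed: int = 0, n_assays: int = 20, **kw) -> FixtureSpec:
    """A spec for multi-assay summarization at desk scale."""
    return replace(FixtureSpec(seed=seed), n_assays=n_assays, **kw)


def gen_chemicals(spec: FixtureSpec) -> list:
    """Synthetic chemicals with CASRN-shaped identifiers."""
    return [Chemical(casrn=f"{1000 + i}-00-{i % 10}", name=f"chem_{i:02d}")
            for i in range(spec.n_chemicals)]


def gen_regions(spec: FixtureSpec) -> list:
    """Unit-square grid polygons with ids SYN001, SYN002, ..."""
    ncols = math.ceil(math.sqrt(spec.n_regions))
    regions = []
    for i in range(spec.n_regions):
        r, c = divmod(i, ncols)
        regions.append(Region(region_id=f"SYN{i + 1:03d}",
                              geometry=sgeom.box(c, -r - 1, c + 1, -r)))
    return regions


def gen_concresp(spec: FixtureSpec) -> tuple:
    """Concentration-response records plus the true-curve table.

    Responses are ``hill_forward(c) + Normal(0, noise_sd)`` at a log-spaced
    concentration grid, per chemical x assay.  Returns (records, truth) where
    truth has one row per chemical x assay with the generating (tp, ga, gw).
    """
    rng = RNGHandle(spec.seed).stream("fixture:concresp")
    chems = gen_chemicals(spec)
    rec_rows, truth_rows = [], []
    conc = np.array(spec.conc_grid, dtype=float)
    for a in range(spec.n_assays):
        assay = f"ASSAY{a + 1:03d}"
        for chem in chems:
            tp = rng.uniform(*spec.tp_range)
            l10ga = rng.uniform(*spec.log10_ga_range)
            gw = rng.uniform(*spec.gw_range)
            curve = HillCurve(tp=tp, ga=10.0 ** l10ga, gw=gw)
            for _ in range(spec.n_reps):
                resp = hill_forward(conc, curve) + rng.normal(0, spec.noise_sd, conc.size)
                rec_rows.append(pd.DataFrame({
                    "casrn": chem.casrn, "assay": assay,
                    "conc": conc, "resp": resp, "hit": True}))
            truth_rows.append({"casrn": chem.casrn, "assay": assay,
                               "tp": tp, "log10_ga": l10ga, "gw": gw})
    return pd.concat(rec_rows, ignore_index=True), pd.DataFrame(truth_rows)


def gen_population_inputs(spec: FixtureSpec) -> dict:
    """Schema-valid exposure, age, obesity, inhalation-rate, and Css tables.

    Css samples are lognormal per stratum with recorded (meanlog, sdlog);
    the returned dict also carries a ``css_truth`` table of those parameters.
    """
    handle = RNGHandle(spec.seed)
    chems = gen_chemicals(spec)
    regions = gen_regions(spec)

    rng = handle.stream("fixture:exposure")
    exp_rows = []
    for reg in regions:
        for chem in chems:
            mean = rng.uniform(*spec.exposure_mean_range)
            exp_rows.append({"region_id": reg.region_id, "casrn": chem.casrn,
                             "mean": mean, "sd": spec.exposure_cv * mean})
    exposure = pd.DataFrame(exp_rows)

    rng = handle.stream("fixture:age")
    age_rows = []
    for reg in regions:
        w = np.array(_AGE_WEIGHTS, dtype=float)
        w = w * rng.uniform(0.8, 1.2, w.size)
        counts = np.round(spec.region_population * w / w.sum()).astype(int)
        counts = np.maximum(counts, 1)
        for (lo, hi), cnt in zip(spec.age_groups, counts):
            age_rows.append({"region_id": reg.region_id, "age_lo": lo,
                             "age_hi": hi, "count": int(cnt)})
    age = pd.DataFrame(age_rows)

    rng = handle.stream("fixture:obesity")
    ob_rows = []
    for reg in regions:
        prev = rng.uniform(*spec.obesity_prev_range)
        half = min(spec.obesity_ci_halfwidth, prev, 100 - prev)
        ob_rows.append({"region_id": reg.region_id, "prev": prev,
                        "ci_lo": prev - half, "ci_hi": prev + half})
    obesity = pd.DataFrame(ob_rows)

    ir = pd.DataFrame(_IR_BRACKETS, columns=["age_lo", "age_hi", "ir_mean", "ir_sd"])

    rng = handle.stream("fixture:css")
    css_rows, truth_rows = [], []
    for chem in chems:
        base = rng.uniform(*spec.css_meanlog_range)
        for (lo, hi) in spec.age_groups:
            for status in ("Normal", "Obese"):
                # obesity and age shift toxicokinetics: modest meanlog offsets
                meanlog = base + (0.2 if status == "Obese" else 0.0) + 0.002 * lo
                samples = rng.lognormal(meanlog, spec.css_sdlog, spec.n_css_samples)
                grp = f"{lo}-{hi}"
                css_rows.append(pd.DataFrame({
                    "casrn": chem.casrn, "age_group": grp,
                    "weight_status": status, "css": samples}))
                truth_rows.append({"casrn": chem.casrn, "age_group": grp,
                                   "weight_status": status,
                                   "meanlog": meanlog, "sdlog": spec.css_sdlog})
    css = pd.concat(css_rows, ignore_index=True)

    return {"exposure": exposure, "age": age, "obesity": obesity, "ir": ir,
            "css": css, "css_truth": pd.DataFrame(truth_rows),
            "regions": regions, "chemicals": chems}


def write_fixture_dir(spec: FixtureSpec, path) -> Path:
    """Write a complete, reader-valid input directory plus truth tables."""
    from . import io_formats
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    inputs = gen_population_inputs(spec)
    concresp, truth = gen_concresp(spec)
    io_formats.write_regions(inputs["regions"], path / "regions.geojson")
    for name in ("exposure", "age", "obesity", "ir", "css"):
        inputs[name].to_csv(path / f"{name}.csv", index=False)
    concresp.to_csv(path / "concresp.csv", index=False)
    truth.to_csv(path / "hill_truth.csv", index=False)
    inputs["css_truth"].to_csv(path / "css_truth.csv", index=False)
    pd.DataFrame([{"casrn": c.casrn, "name": c.name}
                  for c in inputs["chemicals"]]).to_csv(path / "chemicals.csv",
                                                        index=False)
    return path
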