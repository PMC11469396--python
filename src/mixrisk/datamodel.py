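"""Typed containers for every stage of the source-to-outcome pipeline.

The central object is :class:`PipelineState`, which accumulates the inputs
(regions, exposure / demographic / toxicokinetic tables), the fitted Hill
parameters, the simulated population per region, the mixture responses per
region x assay, and sensitivity results.  It mirrors the staged structure of
the analysis: external exposure -> internal dose -> in-vitro-equivalent
concentration -> concentration-response -> mixture risk metric -> map.

All matrices over chemicals share one fixed column order: the sorted CASRN
order of the state's chemical set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Chemical",
    "Region",
    "HillParams",
    "PopulationDraw",
    "MixtureResult",
    "Config",
    "PipelineState",
    "summarize_state",
    "METRICS",
]

#: Recognized per-individual risk metrics.
METRICS = ("GCA.Eff", "IA.Eff", "GCA.HQ", "IA.HQ")


@dataclass(frozen=True)
class Chemical:
    """A chemical identified by its CAS registry number.

    The CASRN is the join key across the exposure, Css, and
    concentration-response tables; an analysis can only use chemicals present
    in all three.
    """

    casrn: str
    name: str = ""

    def __post_init__(self):
        if not self.casrn:
            raise ValueError("casrn must be non-empty")


@dataclass
class Region:
    """A geographic unit (e.g. a 5-digit county FIPS) with optional geometry."""

    region_id: str
    geometry: Optional[object] = None  # shapely geometry

    def __post_init__(self):
        if not self.region_id:
            raise ValueError("region_id must be non-empty")
        if self.geometry is not None and not self.geometry.is_valid:
            raise ValueError(f"region {self.region_id!r}: invalid geometry")


@dataclass
class HillParams:
    """Fitted Hill concentration-response parameters for one chemical x assay.

    ``tp`` is the top (maximal response, % activity), ``log10_ga`` the log10
    AC50 (log10 uM), ``gw`` the Hill coefficient, ``sigma`` the residual scale.
    A 2-parameter fit fixes ``gw = 1`` exactly.
    """

    casrn: str
    assay: str
    tp: float
    log10_ga: float
    gw: float
    sigma: float
    se_tp: float = np.nan
    se_log10_ga: float = np.nan
    se_gw: float = np.nan
    converged: bool = True
    n_params: int = 3

    def __post_init__(self):
        if self.tp <= 0:
            raise ValueError(f"tp must be > 0, got {self.tp}")
        if self.gw <= 0:
            raise ValueError(f"gw must be > 0, got {self.gw}")
        if self.n_params not in (2, 3):
            raise ValueError("n_params must be 2 or 3")
        if self.n_params == 2 and self.gw != 1.0:
            raise ValueError("2-parameter fit requires gw == 1 exactly")

    @property
    def ga(self) -> float:
        """AC50 on the linear scale (uM)."""
        return 10.0 ** self.log10_ga


def _as_2d(x, name, n, n_chem):
    x = np.asarray(x, dtype=float)
    if x.shape != (n, n_chem):
        raise ValueError(f"{name} must have shape ({n}, {n_chem}), got {x.shape}")
    return x


@dataclass
class PopulationDraw:
    """Simulated individuals for one region.

    Individuals are anonymous row indices.  All arrays share the individual
    dimension ``n``; chemical matrices share the state's sorted-CASRN column
    order.  ``d_int`` and ``c_invitro`` are elementwise products of upstream
    fields and are re-derivable; ``validate`` checks consistency.
    """

    region_id: str
    age: np.ndarray                      # integer years, (n,)
    obese: np.ndarray                    # bool, (n,)
    ir: np.ndarray                       # inhalation rate m3/day/kg, (n,)
    casrns: list                         # chemical column order
    c_ext: np.ndarray                    # ug/m3, (n, n_chem)
    css: Optional[np.ndarray] = None     # uM per mg/kg/day, (n, n_chem)
    d_int: Optional[np.ndarray] = None   # mg/kg/day, (n, n_chem)
    c_invitro: Optional[np.ndarray] = None  # uM, (n, n_chem)
    points: Optional[np.ndarray] = None  # optional (n, 2) lon/lat

    def __post_init__(self):
        self.age = np.asarray(self.age, dtype=int)
        self.obese = np.asarray(self.obese, dtype=bool)
        self.ir = np.asarray(self.ir, dtype=float)
        n = self.age.shape[0]
        for nm in ("obese", "ir"):
            if getattr(self, nm).shape != (n,):
                raise ValueError(f"{nm} must have shape ({n},)")
        k = len(self.casrns)
        self.c_ext = _as_2d(self.c_ext, "c_ext", n, k)
        for nm in ("css", "d_int", "c_invitro"):
            v = getattr(self, nm)
            if v is not None:
                setattr(self, nm, _as_2d(v, nm, n, k))
        if np.any(self.ir < 0):
            raise ValueError("ir must be >= 0")
        if np.any(self.c_ext < 0):
            raise ValueError("c_ext must be >= 0")

    @property
    def n(self) -> int:
        return self.age.shape[0]

    def validate(self, time_days: float = 1.0, dose_scaling: float = 1e-3,
                 atol: float = 1e-10):
        """Check that d_int and c_invitro equal their defining products."""
        if self.d_int is not None:
            expect = self.c_ext * self.ir[:, None] * time_days * dose_scaling
            if not np.allclose(self.d_int, expect, atol=atol, rtol=1e-9):
                raise ValueError(f"region {self.region_id}: d_int inconsistent "
                                 "with c_ext * ir * time * scaling")
        if self.c_invitro is not None:
            if self.d_int is None or self.css is None:
                raise ValueError("c_invitro set without d_int and css")
            if not np.allclose(self.c_invitro, self.d_int * self.css,
                               atol=atol, rtol=1e-9):
                raise ValueError(f"region {self.region_id}: c_invitro "
                                 "inconsistent with d_int * css")


@dataclass
class MixtureResult:
    """Per-individual mixture responses for one region x assay."""

    region_id: str
    assay: str
    gca_eff: np.ndarray   # % activity
    ia_eff: np.ndarray    # % activity
    gca_hq: np.ndarray    # dimensionless
    ia_hq: np.ndarray     # dimensionless
    emax: float = np.nan  # assay ceiling used for IA

    def __post_init__(self):
        for nm in ("gca_eff", "ia_eff", "gca_hq", "ia_hq"):
            setattr(self, nm, np.asarray(getattr(self, nm), dtype=float))
        n = self.gca_eff.shape[0]
        for nm in ("ia_eff", "gca_hq", "ia_hq"):
            if getattr(self, nm).shape != (n,):
                raise ValueError(f"{nm} must have shape ({n},)")
        if np.isfinite(self.emax) and np.any(self.ia_eff > self.emax * (1 + 1e-9)):
            raise ValueError("ia_eff exceeds Emax")
        if np.any(self.ia_eff < -1e-12):
            raise ValueError("ia_eff must be >= 0")
        finite_hq = np.concatenate([self.gca_hq[np.isfinite(self.gca_hq)],
                                    self.ia_hq[np.isfinite(self.ia_hq)]])
        if finite_hq.size and np.any(finite_hq < 0):
            raise ValueError("hazard quotients must be >= 0")

    @property
    def n(self) -> int:
        return self.gca_eff.shape[0]

    def metric(self, name: str) -> np.ndarray:
        try:
            attr = {"GCA.Eff": "gca_eff", "IA.Eff": "ia_eff",
                    "GCA.HQ": "gca_hq", "IA.HQ": "ia_hq"}[name]
        except KeyError:
            raise ValueError(f"unknown metric {name!r}; expected one of {METRICS}")
        return getattr(self, attr)


@dataclass
class Config:
    """Run-level configuration.

    ``time_days`` defaults to 1 because the plasma concentration is a
    steady-state estimate; ``dose_scaling`` converts ug to mg in the internal
    dose; ``hq_fraction`` is the benchmark fraction of the limiting mixture
    response defining the hazard-quotient reference dose.
    """

    seed: int = 0
    n_per_region: int = 100
    time_days: float = 1.0
    dose_scaling: float = 1e-3
    hq_fraction: float = 0.10
    assay_quantiles: tuple = (0.10, 0.50, 0.90)
    summary_quantiles: tuple = (0.05, 0.10)
    metric: str = "GCA.Eff"
    n_hill_params: int = 2
    error_model: str = "normal"
    emax: Optional[float] = None  # IA ceiling; None -> max fitted tp per assay
    css_age_groups: tuple = ((0, 17), (18, 44), (45, 64), (65, 100))

    def __post_init__(self):
        if self.n_per_region < 1:
            raise ValueError("n_per_region must be >= 1")
        for q in tuple(self.assay_quantiles) + tuple(self.summary_quantiles):
            if not 0 < q < 1:
                raise ValueError(f"quantile probabilities must be in (0,1), got {q}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if not 0 < self.hq_fraction < 1:
            raise ValueError("hq_fraction must be in (0,1)")
        self.assay_quantiles = tuple(float(q) for q in self.assay_quantiles)
        self.summary_quantiles = tuple(float(q) for q in self.summary_quantiles)
        self.css_age_groups = tuple((int(a), int(b)) for a, b in self.css_age_groups)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assay_quantiles"] = list(self.assay_quantiles)
        d["summary_quantiles"] = list(self.summary_quantiles)
        d["css_age_groups"] = [list(g) for g in self.css_age_groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class PipelineState:
    """Everything a pipeline run knows, from inputs to results."""

    config: Config = field(default_factory=Config)
    regions: list = field(default_factory=list)            # list[Region]
    chemicals: list = field(default_factory=list)          # list[Chemical]
    exposure: Optional[pd.DataFrame] = None
    age: Optional[pd.DataFrame] = None
    obesity: Optional[pd.DataFrame] = None
    ir: Optional[pd.DataFrame] = None
    css: Optional[pd.DataFrame] = None
    concresp: Optional[pd.DataFrame] = None
    hill_params: list = field(default_factory=list)        # list[HillParams]
    population: dict = field(default_factory=dict)         # region_id -> PopulationDraw
    responses: dict = field(default_factory=dict)          # (region_id, assay) -> MixtureResult
    sensitivity: dict = field(default_factory=dict)        # param -> DataFrame

    @property
    def casrns(self) -> list:
        """Fixed chemical column order: sorted CASRN."""
        return sorted(c.casrn for c in self.chemicals)

    @property
    def assays(self) -> list:
        return sorted({hp.assay for hp in self.hill_params})

    def check_joinable(self):
        """Every chemical used by responses must exist in hill_params,
        exposure, and css (the three-way join)."""
        if not self.responses:
            return
        fit = {hp.casrn for hp in self.hill_params}
        exp = set(self.exposure["casrn"]) if self.exposure is not None else set()
        css = set(self.css["casrn"]) if self.css is not None else set()
        usable = fit & exp & css
        if not usable:
            raise ValueError("no chemicals joinable across hill_params, "
                             "exposure, and css tables")

    # -- serialization ---------------------------------------------------

    def save(self, path) -> None:
        """Write the state as CSV tables plus a JSON manifest."""
        from . import io_formats
        io_formats.save_state(self, path)

    @classmethod
    def load(cls, path) -> "PipelineState":
        from . import io_formats
        return io_formats.load_state(path)

    def summary(self) -> str:
        return summarize_state(self)

    def __repr__(self) -> str:
        return self.summary()


def summarize_state(state: PipelineState) -> str:
    """Human-readable account of which pipeline fields are populated."""
    lines = []
    nreg = len(state.regions)
    if state.population:
        ns = sorted({p.n for p in state.population.values()})
        pop = (f"{ns[0]} simulated individuals per region" if len(ns) == 1
               else f"{ns[0]}-{ns[-1]} simulated individuals per region")
    else:
        pop = "no simulated population"
    lines.append(f"{nreg} region{'s' if nreg != 1 else ''}, {pop}")
    lines.append(f"chemicals: {len(state.chemicals)}   assays: {len(state.assays)}")

    def status(obj, dims=""):
        return f"present{dims}" if obj is not None and (not hasattr(obj, '__len__') or len(obj)) else "absent"

    table_dims = lambda df: f" [{len(df)} rows]" if df is not None else ""
    for nm in ("exposure", "age", "obesity", "ir", "css", "concresp"):
        df = getattr(state, nm)
        lines.append(f"  {nm:<12} {status(df, table_dims(df))}")
    lines.append(f"  {'hill_params':<12} "
                 f"{status(state.hill_params, f' [{len(state.hill_params)} fits]' if state.hill_params else '')}")
    lines.append(f"  {'population':<12} "
                 f"{status(state.population, f' [{len(state.population)} regions]' if state.population else '')}")
    lines.append(f"  {'responses':<12} "
                 f"{status(state.responses, f' [{len(state.responses)} region x assay]' if state.responses else '')}")
    lines.append(f"  {'sensitivity':<12} "
                 f"{status(state.sensitivity, f' [{len(state.sensitivity)} parameters]' if state.sensitivity else '')}")
    return "\n".join(lines)
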