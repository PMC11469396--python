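"""Readers and writers for the pipeline's tabular and geospatial formats.

CSV tables (RFC 4180, UTF-8, '.' decimal) carry fixed snake_case headers;
regions and result maps travel as RFC 7946 GeoJSON (WGS84, no reprojection).
Every reader validates its schema and rejects the whole file on any
violation — a file never yields a partially-loaded state.  Concentrations
are stored linear (uM); log transforms happen only inside fitting.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import shapely.geometry as sgeom

from .datamodel import (Chemical, Config, HillParams, MixtureResult,
                        PipelineState, PopulationDraw, Region)

__all__ = [
    "SchemaError",
    "read_regions", "write_regions",
    "read_exposure", "read_age", "read_obesity", "read_ir",
    "read_css", "read_concresp",
    "write_region_results",
    "save_state", "load_state",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


class SchemaError(ValueError):
    """A file violated its declared schema; nothing was loaded."""


# ---------------------------------------------------------------------------
# GeoJSON regions

def read_regions(path, id_property: str = "region_id") -> list:
    """Read a GeoJSON FeatureCollection into Regions, preserving order."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    feats = gj.get("features", [])
    if not feats:
        log.warning("%s: empty FeatureCollection", path)
    regions = []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_property not in props:
            raise SchemaError(f"{path}: feature {i} missing {id_property}")
        geom = feat.get("geometry")
        regions.append(Region(region_id=str(props[id_property]),
                              geometry=sgeom.shape(geom) if geom else None))
    return regions


def write_regions(regions, path, properties=None, id_property: str = "region_id"):
    """Write Regions (plus optional extra per-region properties) as GeoJSON.

    ``properties`` maps region_id -> dict of extra properties.
    """
    feats = []
    for r in regions:
        props = {id_property: r.region_id}
        if properties:
            props.update(properties.get(r.region_id, {}))
        feats.append({
            "type": "Feature",
            "properties": props,
            "geometry": sgeom.mapping(r.geometry) if r.geometry is not None else None,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def write_region_results(summaries: pd.DataFrame, regions, path):
    """Write regional quantile summaries as a GeoJSON choropleth source.

    ``summaries`` has columns region_id, metric, prob, value; each feature
    gets one property per metric-quantile, named like ``GCA.Eff_q50``.
    """
    known = {r.region_id for r in regions}
    unknown = sorted(set(summaries["region_id"]) - known)
    if unknown:
        raise SchemaError(f"summaries reference unknown regions: {unknown}")
    if not np.all(np.isfinite(summaries["value"])):
        raise SchemaError("summary values must be finite")
    props = {}
    for row in summaries.itertuples(index=False):
        key = f"{row.metric}_q{round(row.prob * 100):g}"
        props.setdefault(row.region_id, {})[key] = float(row.value)
    write_regions(regions, path, properties=props)


# ---------------------------------------------------------------------------
# CSV tables

def _read_csv(path, columns) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _fail_rows(path, df, bad_mask, message):
    rows = df.index[np.asarray(bad_mask)].tolist()
    raise SchemaError(f"{path}: {message} (rows {rows})")


def read_exposure(path) -> pd.DataFrame:
    """Per-region per-chemical exposure (columns region_id, casrn, mean, sd; ug/m3)."""
    df = _read_csv(path, ["region_id", "casrn", "mean", "sd"])
    df["region_id"] = df["region_id"].astype(str)
    bad = (df["mean"] < 0) | (df["sd"] < 0)
    if bad.any():
        _fail_rows(path, df, bad, "exposure mean/sd must be >= 0")
    return df


def read_age(path) -> pd.DataFrame:
    """Binned age counts (columns region_id, age_lo, age_hi, count)."""
    df = _read_csv(path, ["region_id", "age_lo", "age_hi", "count"])
    df["region_id"] = df["region_id"].astype(str)
    bad = (df["count"] < 0) | (df["age_lo"] > df["age_hi"])
    if bad.any():
        _fail_rows(path, df, bad, "age bins need count >= 0 and age_lo <= age_hi")
    for rid, g in df.groupby("region_id"):
        g = g.sort_values("age_lo")
        if (g["age_lo"].to_numpy()[1:] <= g["age_hi"].to_numpy()[:-1]).any():
            raise SchemaError(f"{path}: overlapping age bins in region {rid}")
        if not (g["count"] > 0).any():
            raise SchemaError(f"{path}: region {rid} has no positive age-bin count")
    return df


def read_obesity(path) -> pd.DataFrame:
    """Obesity prevalence (columns region_id, prev, ci_lo, ci_hi; crude %)."""
    df = _read_csv(path, ["region_id", "prev", "ci_lo", "ci_hi"])
    df["region_id"] = df["region_id"].astype(str)
    bad = ~((df["ci_lo"] >= 0) & (df["ci_lo"] <= df["prev"])
            & (df["prev"] <= df["ci_hi"]) & (df["ci_hi"] <= 100))
    if bad.any():
        _fail_rows(path, df, bad, "need 0 <= ci_lo <= prev <= ci_hi <= 100")
    return df


def read_ir(path) -> pd.DataFrame:
    """Age-bracketed inhalation rates (columns age_lo, age_hi, ir_mean, ir_sd).

    Brackets must partition the integer ages [0, 100].
    """
    df = _read_csv(path, ["age_lo", "age_hi", "ir_mean", "ir_sd"])
    bad = (df["ir_mean"] <= 0) | (df["ir_sd"] < 0)
    if bad.any():
        _fail_rows(path, df, bad, "need ir_mean > 0 and ir_sd >= 0")
    g = df.sort_values("age_lo")
    lo, hi = g["age_lo"].to_numpy(int), g["age_hi"].to_numpy(int)
    if lo[0] > 0 or hi[-1] < 100 or (lo[1:] != hi[:-1] + 1).any():
        raise SchemaError(f"{path}: inhalation-rate brackets must partition [0, 100]")
    return df


def read_css(path) -> pd.DataFrame:
    """Css bootstrap samples (columns casrn, age_group, weight_status, css).

    One sample per row; every (age_group x weight_status) cell must exist for
    every chemical, with non-negative samples.
    """
    df = _read_csv(path, ["casrn", "age_group", "weight_status", "css"])
    bad = df["css"] < 0
    if bad.any():
        _fail_rows(path, df, bad, "Css samples must be >= 0")
    bad_status = ~df["weight_status"].isin(["Normal", "Obese"])
    if bad_status.any():
        _fail_rows(path, df, bad_status, "weight_status must be Normal or Obese")
    groups = sorted(df["age_group"].unique())
    have = set(map(tuple, df[["casrn", "age_group", "weight_status"]]
                   .drop_duplicates().itertuples(index=False)))
    for cas in sorted(df["casrn"].unique()):
        for grp in groups:
            for st in ("Normal", "Obese"):
                if (cas, grp, st) not in have:
                    raise SchemaError(f"{path}: chemical {cas} missing Css cell "
                                      f"({st} x {grp})")
    return df


def read_concresp(path) -> pd.DataFrame:
    """Concentration-response records (columns casrn, assay, conc, resp[, hit]).

    Concentrations are uM (> 0 except vehicle-control zeros); each chemical x
    assay needs >= 4 distinct concentrations for fitting.
    """
    df = _read_csv(path, ["casrn", "assay", "conc", "resp"])
    bad = (df["conc"] < 0) | ~np.isfinite(df["resp"])
    if bad.any():
        _fail_rows(path, df, bad, "need conc >= 0 and finite resp")
    for (cas, assay), g in df.groupby(["casrn", "assay"]):
        if g.loc[g["conc"] > 0, "conc"].nunique() < 4:
            raise SchemaError(f"{path}: {cas} x {assay} has fewer than 4 "
                              "distinct positive concentrations")
    return df


# ---------------------------------------------------------------------------
# state serialization: directory of CSVs + one JSON manifest

def _population_frame(pop: PopulationDraw) -> pd.DataFrame:
    df = pd.DataFrame({"region_id": pop.region_id,
                       "age": pop.age, "obese": pop.obese, "ir": pop.ir})
    for stem, mat in (("c_ext", pop.c_ext), ("css", pop.css),
                      ("d_int", pop.d_int), ("c_invitro", pop.c_invitro)):
        if mat is not None:
            for j, cas in enumerate(pop.casrns):
                df[f"{stem}:{cas}"] = mat[:, j]
    return df


def _population_from_frame(g: pd.DataFrame, casrns) -> PopulationDraw:
    def mat(stem):
        cols = [f"{stem}:{cas}" for cas in casrns]
        if not all(c in g.columns for c in cols):
            return None
        return g[cols].to_numpy(float)
    return PopulationDraw(
        region_id=str(g["region_id"].iloc[0]),
        age=g["age"].to_numpy(int), obese=g["obese"].to_numpy(bool),
        ir=g["ir"].to_numpy(float), casrns=list(casrns),
        c_ext=mat("c_ext"), css=mat("css"),
        d_int=mat("d_int"), c_invitro=mat("c_invitro"))


def save_state(state: PipelineState, path):
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": state.config.to_dict(),
        "chemicals": [{"casrn": c.casrn, "name": c.name} for c in state.chemicals],
        "n_regions": len(state.regions),
        "fields": {},
    }

    def csv(df, name):
        df.to_csv(path / f"{name}.csv", index=False, float_format=_FLOAT_FMT)
        manifest["fields"][name] = list(df.shape)

    if state.regions:
        write_regions(state.regions, path / "regions.geojson")
        manifest["fields"]["regions"] = [len(state.regions)]
    for name in ("exposure", "age", "obesity", "ir", "css", "concresp"):
        df = getattr(state, name)
        if df is not None:
            csv(df, name)
    if state.hill_params:
        from .dose_response import hill_params_frame
        csv(hill_params_frame(state.hill_params), "hill_params")
    if state.population:
        frames = [_population_frame(state.population[rid])
                  for rid in sorted(state.population)]
        csv(pd.concat(frames, ignore_index=True), "population")
    if state.responses:
        from .mixture import responses_frame
        csv(responses_frame(state.responses), "responses")
    if state.sensitivity:
        frames = [df.assign(param=param)
                  for param, df in sorted(state.sensitivity.items())]
        csv(pd.concat(frames, ignore_index=True), "sensitivity")
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_state(path) -> PipelineState:
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    state = PipelineState(config=Config.from_dict(manifest["config"]))
    state.chemicals = [Chemical(**c) for c in manifest["chemicals"]]
    if (path / "regions.geojson").exists():
        state.regions = read_regions(path / "regions.geojson")
    readers = {"exposure": read_exposure, "age": read_age, "obesity": read_obesity,
               "ir": read_ir, "css": read_css, "concresp": read_concresp}
    for name, reader in readers.items():
        f = path / f"{name}.csv"
        if f.exists():
            setattr(state, name, reader(f))
    f = path / "hill_params.csv"
    if f.exists():
        df = pd.read_csv(f, float_precision="round_trip")
        state.hill_params = [
            HillParams(casrn=str(r.casrn), assay=str(r.assay), tp=r.tp,
                       log10_ga=r.log10_ga, gw=r.gw, sigma=r.sigma,
                       se_tp=r.se_tp, se_log10_ga=r.se_log10_ga, se_gw=r.se_gw,
                       converged=bool(r.converged), n_params=int(r.n_params))
            for r in df.itertuples(index=False)]
    f = path / "population.csv"
    if f.exists():
        df = pd.read_csv(f, float_precision="round_trip")
        casrns = state.casrns
        for rid, g in df.groupby("region_id", sort=True):
            state.population[str(rid)] = _population_from_frame(g, casrns)
    f = path / "responses.csv"
    if f.exists():
        df = pd.read_csv(f, float_precision="round_trip")
        for (rid, assay), g in df.groupby(["region_id", "assay"], sort=True):
            wide = g.pivot(index="individual", columns="metric",
                           values="value").sort_index()
            state.responses[(str(rid), str(assay))] = MixtureResult(
                region_id=str(rid), assay=str(assay),
                gca_eff=wide["GCA.Eff"].to_numpy(),
                ia_eff=wide["IA.Eff"].to_numpy(),
                gca_hq=wide["GCA.HQ"].to_numpy(),
                ia_hq=wide["IA.HQ"].to_numpy())
    f = path / "sensitivity.csv"
    if f.exists():
        df = pd.read_csv(f, float_precision="round_trip")
        for param, g in df.groupby("param", sort=True):
            state.sensitivity[str(param)] = g.drop(columns="param").reset_index(drop=True)
    return state
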