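"""Monte Carlo simulation of individuals within a region.

Each simulator draws one per-individual quantity from its documented
distribution: age from binned census-style counts, obesity from a Bernoulli
whose prevalence is itself uncertain (normal within the reported confidence
interval), inhalation rate from an age-bracketed truncated normal, external
exposure from a per-chemical truncated normal, and the steady-state plasma
concentration Css by bootstrap resampling of a per-stratum sample vector
(age group x weight status), standing in for individual toxicokinetic
simulation.

All samplers are deterministic given a Generator and never return negative
values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "simulate_age",
    "simulate_obesity",
    "simulate_inhalation_rate",
    "simulate_exposure",
    "sample_css",
    "age_group_label",
    "DEFAULT_AGE_GROUPS",
]

#: Css strata age brackets (inclusive), matching common toxicokinetic
#: population simulation strata.
DEFAULT_AGE_GROUPS = ((0, 17), (18, 44), (45, 64), (65, 100))


def _truncnorm0(mean, sd, n, rng, upper=np.inf):
    """Draws from Normal(mean, sd) truncated to [0, upper]; sd=0 -> constant."""
    mean = float(mean)
    sd = float(sd)
    if sd == 0:
        return np.full(n, np.clip(mean, 0.0, upper))
    a = (0.0 - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_age(age_bins: pd.DataFrame, n: int, rng: np.random.Generator) -> np.ndarray:
    """Integer ages: bin chosen proportionally to count, uniform within bin.

    ``age_bins`` has columns age_lo, age_hi (inclusive), count for one region.
    """
    lo = age_bins["age_lo"].to_numpy(int)
    hi = age_bins["age_hi"].to_numpy(int)
    counts = age_bins["count"].to_numpy(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all age-bin counts are zero")
    idx = rng.choice(len(lo), size=n, p=counts / total)
    return rng.integers(lo[idx], hi[idx] + 1)


def simulate_obesity(prev: float, ci_lo: float, ci_hi: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Boolean obesity status.

    The reported crude prevalence (%) carries sampling uncertainty: a
    per-individual prevalence is drawn from Normal(prev, CI width / 3.92)
    truncated to [0, 100], then status ~ Bernoulli(p / 100).
    """
    sd = (ci_hi - ci_lo) / 3.92
    if sd == 0:
        p = np.full(n, prev)
    else:
        a = (0.0 - prev) / sd
        b = (100.0 - prev) / sd
        p = stats.truncnorm.rvs(a, b, loc=prev, scale=sd, size=n, random_state=rng)
    return rng.random(n) < p / 100.0


def simulate_inhalation_rate(ages: np.ndarray, ir_table: pd.DataFrame,
                             rng: np.random.Generator) -> np.ndarray:
    """Inhalation rate (m3/day/kg) per individual from its age bracket.

    ``ir_table`` has columns age_lo, age_hi (inclusive), ir_mean, ir_sd.
    """
    ages = np.asarray(ages, dtype=int)
    out = np.full(ages.shape, np.nan)
    assigned = np.zeros(ages.shape, dtype=bool)
    for row in ir_table.itertuples(index=False):
        mask = (ages >= row.age_lo) & (ages <= row.age_hi) & ~assigned
        k = int(mask.sum())
        if k:
            out[mask] = _truncnorm0(row.ir_mean, row.ir_sd, k, rng)
            assigned[mask] = True
    if not assigned.all():
        bad = np.unique(ages[~assigned])
        raise ValueError(f"ages outside all inhalation-rate brackets: {bad.tolist()}")
    return out


def simulate_exposure(exposure: pd.DataFrame, n: int,
                      rng: np.random.Generator) -> tuple:
    """External exposure matrix (n x chemicals, ug/m3), truncated normal.

    ``exposure`` has columns casrn, mean, sd for one region.  Columns follow
    sorted CASRN order; returns (casrns, matrix).
    """
    exposure = exposure.sort_values("casrn")
    casrns = exposure["casrn"].tolist()
    mat = np.empty((n, len(casrns)))
    for j, row in enumerate(exposure.itertuples(index=False)):
        mat[:, j] = _truncnorm0(row.mean, row.sd, n, rng)
    return casrns, mat


def age_group_label(age: int, groups=DEFAULT_AGE_GROUPS) -> str:
    """Stratum label ('lo-hi') for an age under the given brackets."""
    for lo, hi in groups:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"age {age} outside all Css age groups {groups}")


def sample_css(css_table: pd.DataFrame, ages: np.ndarray, obese: np.ndarray,
               rng: np.random.Generator, groups=DEFAULT_AGE_GROUPS) -> tuple:
    """Bootstrap Css (uM per mg/kg/day) per individual x chemical.

    Each individual maps to a stratum (age group x weight status); its Css is
    drawn uniformly with replacement from that stratum's sample vector.
    ``css_table`` has columns casrn, age_group, weight_status, css (one sample
    per row).  Returns (casrns, matrix).
    """
    ages = np.asarray(ages, dtype=int)
    obese = np.asarray(obese, dtype=bool)
    n = ages.shape[0]
    casrns = sorted(css_table["casrn"].unique())
    labels = np.array([age_group_label(a, groups) for a in ages])
    status = np.where(obese, "Obese", "Normal")

    pools = {k: g["css"].to_numpy(float)
             for k, g in css_table.groupby(["casrn", "age_group", "weight_status"])}
    mat = np.empty((n, len(casrns)))
    strata = sorted(set(zip(labels, status)))  # fixed order: reproducible draws
    for j, cas in enumerate(casrns):
        for (lab, st) in strata:
            key = (cas, lab, st)
            if key not in pools:
                raise ValueError(f"Css stratum missing for chemical {cas}, "
                                 f"age group {lab}, weight status {st}")
            mask = (labels == lab) & (status == st)
            mat[mask, j] = rng.choice(pools[key], size=int(mask.sum()), replace=True)
    return casrns, mat
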