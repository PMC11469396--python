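"""Shared fixtures: small synthetic input sets and a completed pipeline run."""

import numpy as np
import pandas as pd
import pytest

from mixrisk.datamodel import Config
from mixrisk.fixtures import FixtureSpec, write_fixture_dir
from mixrisk.pipeline import load_inputs, run_pipeline


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic input directory (4 regions, 5 chemicals, 1 assay)."""
    path = tmp_path_factory.mktemp("inputs")
    spec = FixtureSpec(seed=7, n_regions=4, n_chemicals=5, n_assays=1)
    return write_fixture_dir(spec, path)


@pytest.fixture(scope="session")
def run_state(fixture_dir):
    """A fully-run pipeline state on the session fixture inputs."""
    cfg = Config(seed=7, n_per_region=40)
    state = load_inputs(fixture_dir, cfg)
    return run_pipeline(state)


@pytest.fixture()
def age_bins():
    return pd.DataFrame({"region_id": "R1",
                         "age_lo": [0, 10], "age_hi": [9, 19],
                         "count": [1, 3]})


def make_degenerate_state(css_values, exposure_mean=1.0, tp=100.0, ga=10.0,
                          n=200, seed=0):
    """One region, one chemical, everything deterministic except the Css
    bootstrap pool (``css_values``).  Used by sensitivity enumeration tests."""
    from mixrisk.datamodel import Chemical, HillParams, PipelineState, Region

    state = PipelineState(config=Config(
        seed=seed, n_per_region=n, css_age_groups=((0, 100),)))
    state.regions = [Region(region_id="R1")]
    state.chemicals = [Chemical(casrn="50-00-0", name="x")]
    state.exposure = pd.DataFrame({"region_id": ["R1"], "casrn": ["50-00-0"],
                                   "mean": [exposure_mean], "sd": [0.0]})
    state.age = pd.DataFrame({"region_id": ["R1"], "age_lo": [30],
                              "age_hi": [30], "count": [100]})
    state.obesity = pd.DataFrame({"region_id": ["R1"], "prev": [0.0],
                                  "ci_lo": [0.0], "ci_hi": [0.0]})
    state.ir = pd.DataFrame({"age_lo": [0], "age_hi": [100],
                             "ir_mean": [0.25], "ir_sd": [0.0]})
    state.css = pd.DataFrame({
        "casrn": "50-00-0", "age_group": "0-100",
        "weight_status": np.repeat(["Normal", "Obese"], len(css_values)),
        "css": np.tile(np.asarray(css_values, float), 2)})
    state.hill_params = [HillParams(casrn="50-00-0", assay="A1", tp=tp,
                                    log10_ga=np.log10(ga), gw=1.0, sigma=1.0,
                                    se_tp=0.0, se_log10_ga=0.0, se_gw=0.0,
                                    n_params=2)]
    return state
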