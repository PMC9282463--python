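import numpy as np
import pandas as pd
import pytest

from cpuestd.cpue import compute_indices, filter_records
from cpuestd.effects import TrueEffects
from cpuestd.geometry import GeometryConfig, make_study_geometry
from cpuestd.management import make_management_timeline
from cpuestd.simulate import SurveyPlan, simulate_survey_series


@pytest.fixture(scope="session")
def geometry():
    return make_study_geometry(GeometryConfig())


@pytest.fixture(scope="session")
def timeline():
    return make_management_timeline()


@pytest.fixture(scope="session")
def effects():
    return TrueEffects()


@pytest.fixture(scope="session")
def survey_dataset(geometry, timeline, effects):
    """One standard synthetic two-series dataset (seed 7), filtered."""
    hauls, env_fields = simulate_survey_series(
        geometry, timeline, effects, SurveyPlan(), seed=7)
    table = compute_indices(hauls)
    filtered, report = filter_records(table)
    return {"hauls": hauls, "table": table, "filtered": filtered,
            "report": report, "env_fields": env_fields}


def make_gamma_data(n=120, seed=0, slope=1.0, factor_effect=0.5,
                    shape=4.0, extra_null=False):
    """Simple Gamma/log regression dataset for engine-level tests."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n)
    f = rng.choice(["a", "b"], n)
    eta = 1.0 + slope * x + factor_effect * (f == "b")
    d = {"x": x, "f": f,
         "y": rng.gamma(shape, np.exp(eta) / shape)}
    if extra_null:
        d["xnull"] = rng.uniform(0.0, 1.0, n)
    return pd.DataFrame(d)
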