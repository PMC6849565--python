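import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import traitsoil as ts

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment at the default study conditions."""
    return ts.simulate_experiment(ts.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def three_syndrome_traits(default_experiment):
    """Trait table with three well-separated syndromes + generating labels."""
    return default_experiment.traits, default_experiment.true_groups


@pytest.fixture()
def tiny_traits():
    """Hand-written trait table for arithmetic checks."""
    return pd.DataFrame({
        "species_id": ["a", "b", "c", "d"],
        "height": [10.0, 30.0, 2.0, 6.0],
        "perenniality": [1, 5, 3, 3],
        "sla": [20.0, 20.0, 10.0, 15.0],
        "root_architecture": [1, 8, 4, 4],
        "root_depth": [1, 3, 2, 2],
        "mycorrhizal_affinity": [1, 3, 2, 2],
    })


def make_survey(cover: dict[str, float], subplot="s1", month="July"):
    return pd.DataFrame({
        "subplot_id": subplot,
        "survey_month": month,
        "species_id": list(cover),
        "cover_pct": list(cover.values()),
    })


@pytest.fixture()
def survey_factory():
    return make_survey
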