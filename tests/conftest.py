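import numpy as np
import pandas as pd
import pytest

from ptsdpanel.core import FeatureMatrix, SampleRecord
from ptsdpanel.simulate import SimulationConfig, generate_study


def tiny_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Small, fast study: ~60 features, full default cohort sizes."""
    defaults = dict(
        n_features_per_type={
            "methylation": 15, "mirna": 10, "protein": 10,
            "metabolite": 10, "clinical_lab": 10, "physiological": 5,
        },
        n_informative=6,
        effect_sizes=[1.5] * 6,
        effect_directions=[1, -1, 1, -1, 1, -1],
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_study():
    return generate_study(tiny_sim_config(seed=7))


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(size=(8, 4)),
        index=[f"s{i}" for i in range(8)],
        columns=["prot_a", "prot_b", "metab_a", "phys_a"],
    )
    types = {"prot_a": "protein", "prot_b": "protein",
             "metab_a": "metabolite", "phys_a": "physiological"}
    return FeatureMatrix(values=values.abs() + 1.0, feature_types=types)


def make_record(**overrides) -> SampleRecord:
    defaults = dict(
        sample_id="s1", subject_id="subjA", cohort="discovery",
        label="ptsd", caps_total=68.0,
        caps_subscales={"reexperiencing": 25.0, "avoidance": 20.0,
                        "hyperarousal": 23.0},
        ethnicity="hispanic", mdd=False, timepoint="T0",
    )
    defaults.update(overrides)
    return SampleRecord(**defaults)
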