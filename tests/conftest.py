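import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import turbofilter as tf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def carboxylase_ref() -> tf.ReferenceSet:
    return tf.ReferenceSet(
        name="carboxylases",
        protein_ids=frozenset({"PYC-1", "PCCA-1", "MCCC-1", "POD-2"}),
    )


def make_matrix(values: dict, samples=None) -> tf.IntensityMatrix:
    """Build a matrix from {protein: {run: intensity-or-None}}."""
    df = pd.DataFrame(values).T.astype(float)
    return tf.IntensityMatrix(df, samples)


@pytest.fixture
def small_contrast():
    """3 bait + 3 control runs with hand-placed detection patterns."""
    runs_b = ["b1", "b2", "b3"]
    runs_c = ["c1", "c2", "c3"]
    nan = np.nan
    values = {
        "ENRICHED": {"b1": 40.0, "b2": 44.0, "b3": 36.0, "c1": 10.0, "c2": 11.0, "c3": 9.0},
        "FLAT": {"b1": 20.0, "b2": 21.0, "b3": 19.0, "c1": 20.0, "c2": 21.0, "c3": 19.0},
        "BAITONLY": {"b1": 900.0, "b2": 1000.0, "b3": 1100.0, "c1": nan, "c2": nan, "c3": nan},
        "CTRLONLY": {"b1": nan, "b2": nan, "b3": nan, "c1": 50.0, "c2": 55.0, "c3": 45.0},
        "PARTIAL": {"b1": 30.0, "b2": 33.0, "b3": nan, "c1": nan, "c2": nan, "c3": nan},
        "SPARSE": {"b1": 13.0, "b2": nan, "b3": nan, "c1": nan, "c2": nan, "c3": nan},
    }
    return make_matrix(values), runs_b, runs_c


@pytest.fixture(scope="session")
def default_study() -> tf.SimulatedStudy:
    """One seeded study at the default conditions, shared across tests."""
    return tf.simulate_study(tf.SimConfig(seed=11))


def small_sim_config(seed: int, **overrides) -> tf.SimConfig:
    """A fast single-bait study used by property tests."""
    base = dict(
        n_proteins=300,
        n_promiscuous=20,
        baits=(
            tf.BaitSpec("B::TurboID", "B", cis_fc=100.0, partners={"P1": 10.0}),
        ),
        n_experiments=1,
        include_nonspecific_control=False,
        seed=seed,
    )
    base.update(overrides)
    return tf.SimConfig(**base)
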