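import numpy as np
import pandas as pd
import pytest

import gaitmood as gm
from gaitmood.features import AXES, N_FREQS, FeatureMatrix
from gaitmood.preprocess import RETAINED_JOINTS


@pytest.fixture(scope="session")
def strong_model():
    return gm.effect_model("strong")


@pytest.fixture(scope="session")
def null_model():
    return gm.effect_model("none")


@pytest.fixture(scope="session")
def default_params():
    return gm.GaitParameters()


@pytest.fixture(scope="session")
def short_recording(default_params):
    """A 20 s noise-free walk: several front/back passes with turns."""
    params = gm.GaitParameters(noise_sd_m=0.0)
    return gm.generate_recording(params, duration_s=20.0, rng_seed=42)


@pytest.fixture(scope="session")
def segment64(short_recording):
    seg = gm.preprocess_recording(short_recording, rng_seed=7)
    assert seg is not None
    return seg


def random_feature_matrix(n_subjects: int, rng: np.random.Generator) -> FeatureMatrix:
    """A full 4608-column matrix of random values (not normalized)."""
    columns = pd.MultiIndex.from_product(
        [RETAINED_JOINTS, AXES, range(N_FREQS)],
        names=["joint", "axis", "freq_index"],
    )
    data = pd.DataFrame(
        rng.normal(size=(n_subjects, len(columns))),
        index=[f"S{i:04d}" for i in range(n_subjects)],
        columns=columns,
    )
    return FeatureMatrix(data, normalized=False)


def small_feature_matrix(values: np.ndarray) -> FeatureMatrix:
    """Wrap an (n, p) array as a FeatureMatrix using the first p labels."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    triples = [
        (j, a, k) for j in RETAINED_JOINTS for a in AXES for k in range(N_FREQS)
    ][:p]
    columns = pd.MultiIndex.from_tuples(triples, names=["joint", "axis", "freq_index"])
    data = pd.DataFrame(values, index=[f"S{i:04d}" for i in range(n)], columns=columns)
    return FeatureMatrix(data, normalized=True)
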