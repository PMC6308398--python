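import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from physioaffect.features import WindowSpec, build_feature_matrix, normalize_minmax
from physioaffect.simulate import SimParams, simulate_subject


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams(seed=7)


@pytest.fixture(scope="session")
def subject_recordings(default_params):
    """Both conditions of one full-length (60-min) synthetic subject."""
    return simulate_subject(default_params, subject_id="S01")


@pytest.fixture(scope="session")
def feature_matrix(subject_recordings):
    """Raw (unnormalized) 200-row feature matrix of the synthetic subject."""
    return build_feature_matrix(subject_recordings, WindowSpec())


@pytest.fixture(scope="session")
def normalized_matrix(feature_matrix):
    matrix, _ = normalize_minmax(feature_matrix)
    return matrix


@pytest.fixture(scope="session")
def short_params() -> SimParams:
    """A 12-minute subject for cheaper structural tests."""
    return SimParams(duration_s=720, seed=11)


@pytest.fixture(scope="session")
def short_recordings(short_params):
    return simulate_subject(short_params, subject_id="S02")


def planted_signal_matrix(seed: int, n: int = 200, d: int = 16, n_signal: int = 3,
                          shift_sd: float = 3.0):
    """Gaussian features in [0,1]-ish space: the first ``n_signal`` columns
    have a class-mean shift of ``shift_sd`` standard deviations."""
    rng = np.random.default_rng(seed)
    sd = 0.1
    X = rng.normal(0.5, sd, size=(n, d))
    y = np.repeat([0, 1], n // 2)
    X[y == 1, :n_signal] += shift_sd * sd
    X = np.clip(X, 0.0, 1.0)
    return X, y
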