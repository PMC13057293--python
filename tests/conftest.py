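import numpy as np
import pytest

from eegscreen.decomposition import decompose_epochs, epoch_recording, FOUR_BANDS
from eegscreen.features import build_feature_matrix, FeatureMatrix
from eegscreen.io_edf import CANONICAL_CHANNELS, Recording
from eegscreen.synthetic import CohortConfig, generate_cohort, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort_config():
    """2+2 subjects, 40 s each: enough for 4 epochs/subject."""
    return CohortConfig(n_dyslexic=2, n_control=2, duration_s=40.0, seed=7)


@pytest.fixture
def small_recording(small_cohort_config):
    return generate_subject(small_cohort_config, 0, 1)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_dyslexic=2, n_control=2, duration_s=40.0, seed=7)
    recordings, manifest = generate_cohort(cfg)
    return cfg, recordings, manifest


@pytest.fixture(scope="session")
def small_feature_matrix(small_cohort):
    _, recordings, _ = small_cohort
    collections = [
        decompose_epochs(epoch_recording(rec), bands=FOUR_BANDS)
        for rec in recordings
    ]
    return build_feature_matrix(collections, band_set="4band")


def gaussian_feature_matrix(
    n_per_class: int = 60,
    n_features: int = 8,
    effect: float = 0.0,
    n_informative: int = 2,
    seed: int = 0,
) -> FeatureMatrix:
    """Plain Gaussian features with an optional mean shift on the first
    ``n_informative`` columns; labels 0/1, one fake subject per sample."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    X = rng.normal(size=(n, n_features))
    X[y == 1, :n_informative] += effect
    return FeatureMatrix(
        values=X,
        feature_names=[f"f{i}" for i in range(n_features)],
        labels=y,
        subject_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def separable_features():
    return gaussian_feature_matrix(n_per_class=100, n_features=12,
                                   effect=4.0, n_informative=4, seed=3)
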