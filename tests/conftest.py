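import numpy as np
import pytest

from apneafuse.base_models import features_to_array
from apneafuse.preprocessing import apply_zscore, fit_zscore, preprocess_record
from apneafuse.synthetic import SyntheticSpec, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """A noiseless, HRV-free record: 2 minutes/class at 75 bpm (RR = 0.8 s)."""
    spec = SyntheticSpec(
        n_minutes_per_class=2, hrv_sd=0.0, noise_sd=0.0, base_hr=75.0, seed=11
    )
    return generate_record(spec)


@pytest.fixture(scope="session")
def separable_data():
    """Z-scored train/test arrays from well-separated synthetic records.

    Swing 0.4 with mild noise: a strongly separable desk-scale problem
    (100 train + 40 test minutes per class).
    """
    def make(n, seed):
        spec = SyntheticSpec(
            n_minutes_per_class=n, apnea_rr_swing=0.4, noise_sd=0.03, seed=seed
        )
        return preprocess_record(generate_record(spec))

    train_fms = make(100, 21)
    test_fms = make(40, 22)
    stats = fit_zscore(train_fms)
    X, y = features_to_array([apply_zscore(f, stats) for f in train_fms])
    Xt, yt = features_to_array([apply_zscore(f, stats) for f in test_fms])
    return X, y, Xt, yt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
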