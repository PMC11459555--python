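import numpy as np
import pytest

from emgdisc.synth import CohortConfig, generate_cohort
from emgdisc.evaluate import cohort_templates
from emgdisc.temporal import TemporalNetConfig, TemporalNetClassifier


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort: 4 users x 6 gestures x 6 reps."""
    config = CohortConfig(n_users=4, n_reps=6, seed=42)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def tiny_templates(tiny_cohort):
    return cohort_templates(tiny_cohort)


@pytest.fixture(scope="session")
def small_net_config():
    return TemporalNetConfig(
        hidden=16,
        n_lstm_layers=1,
        head_sizes=(16, 8),
        lr=3e-3,
        batch_size=64,
        max_epochs=40,
        min_epochs=10,
        track_train_accuracy=False,
        seed=7,
    )


@pytest.fixture(scope="session")
def trained_net(tiny_templates, small_net_config):
    """A cross-user temporal model trained on 3 of the 4 tiny-cohort users."""
    train = [t for t in tiny_templates if t.user_id != "user0003"]
    clf = TemporalNetClassifier(small_net_config).fit(train)
    return clf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
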