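import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import actiflux as af
from actiflux.simulate import DEFAULT_SIGNAL_PARAMS, SignalParams

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def zero_noise_params() -> dict:
    """Signal parameters with all sensor noise removed: every class has a
    deterministic, disjoint feature signature."""
    return {
        kind: SignalParams(
            p.gravity_unit_vector,
            p.gait_frequency,
            p.gait_amplitude,
            0.0,
            p.table_position_index,
        )
        for kind, p in DEFAULT_SIGNAL_PARAMS.items()
    }


@pytest.fixture(scope="session")
def reference_session():
    """One default-noise labeled reference session plus its features."""
    trace, labels = af.simulate_reference_session("child_a", seed=101)
    feats = af.features_for_trace(trace)
    return trace, labels, feats


@pytest.fixture(scope="session")
def trained_individual(reference_session):
    _, labels, feats = reference_session
    refset = af.ReferenceSet.from_session(feats, labels)
    return af.train_model(refset)


def nearest_centroid_predict(train_X, train_y, X):
    """Independent oracle classifier: assign each frame to the class of
    the nearest training-set centroid (standardized features)."""
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    Ts = (train_X - mu) / sd
    classes = np.unique(train_y)
    cents = np.stack([Ts[train_y == c].mean(axis=0) for c in classes])
    d = ((Xs[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    return classes[np.argmin(d, axis=1)]
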