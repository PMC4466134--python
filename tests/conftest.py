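import numpy as np
import pytest

from einscan import (
    NoiseModel,
    TruthProfile,
    builtin_profile,
    generate_scan,
    normalize_to_reference,
)


@pytest.fixture(scope="session")
def in6():
    return builtin_profile("IN6")


@pytest.fixture(scope="session")
def in13():
    return builtin_profile("IN13")


@pytest.fixture(scope="session")
def in16():
    return builtin_profile("IN16")


@pytest.fixture(scope="session")
def default_truth():
    """Two-population truth with the published 1-ns-instrument force constants."""
    return TruthProfile()


@pytest.fixture(scope="session")
def noise_free_in16_scan(default_truth, in16):
    raw = generate_scan(default_truth, in16, noise=None)
    return normalize_to_reference(raw, 20.0)


@pytest.fixture()
def noisy_in16_scan(default_truth, in16):
    raw = generate_scan(default_truth, in16, noise=NoiseModel(5000.0, seed=42))
    return normalize_to_reference(raw, 20.0)


@pytest.fixture(scope="session")
def toy_raw_scan():
    """Small handmade raw scan: 3 temperatures x 3 Q, strictly positive counts."""
    from einscan import RawScan

    q = np.array([0.5, 1.0, 1.5])
    t = np.array([20.0, 100.0, 300.0])
    i = np.array([[100.0, 90.0, 80.0], [95.0, 85.0, 70.0], [80.0, 60.0, 40.0]])
    return RawScan(q, t, i, np.sqrt(i), metadata={"instrument": "IN16"})
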