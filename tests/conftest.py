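import numpy as np
import pytest

from somno.epoch_data import EpochSeries


def build_series(states, swa=None, artifact=None, phase=None, derivation="frontal"):
    """Small EpochSeries from a list of state codes (test helper)."""
    states = np.asarray(states, dtype="<U2")
    n = states.shape[0]
    if swa is None:
        swa = np.full(n, 100.0)
    if artifact is None:
        artifact = np.zeros(n, dtype=bool)
    if phase is None:
        phase = np.full(n, "L")
    return EpochSeries(
        state=states,
        artifact=np.asarray(artifact, dtype=bool),
        phase=np.asarray(phase, dtype="<U1"),
        swa={derivation: np.asarray(swa, dtype=float)},
    )


@pytest.fixture
def series_factory():
    return build_series


def random_hypnogram(rng, n=500):
    """Uniform state draws; used by the brute-force oracle comparisons."""
    return rng.choice(np.array(["W", "N", "R", "BA"], dtype="<U2"), size=n)


@pytest.fixture(scope="session")
def noisefree_dataset():
    from somno.synthetic import GeneratorConfig, make_dataset

    cfg = GeneratorConfig(seed=1, noise_sigma=0.0, noise_sigma_off=0.0, artifact_rate=0.0)
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    from somno.synthetic import GeneratorConfig, make_dataset

    cfg = GeneratorConfig(seed=1)  # defaults: 15% lognormal noise, 2.8% artifacts
    return make_dataset(cfg)
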