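import numpy as np
import pytest

import semdecode as sd


@pytest.fixture(scope="session")
def config():
    return sd.AnalysisConfig()


@pytest.fixture(scope="session")
def effect_spec():
    """Canonical two-effect session: abstract-dominant IFG response in an
    early-to-mid window, concrete-dominant SM1 response late."""
    return sd.SimulationSpec(
        effects=(
            sd.EffectSpec("IFG", (250.0, 1250.0), "abstract", gain=2.0),
            sd.EffectSpec("SM1", (1000.0, 1500.0), "concrete", gain=2.0),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def effect_session(effect_spec):
    return sd.simulate_session(effect_spec)


@pytest.fixture(scope="session")
def effect_preprocessed(effect_session, config):
    rec, events, electrodes = effect_session
    binned, epochs = sd.preprocess_session(rec, events, config)
    return binned, epochs, electrodes


@pytest.fixture(scope="session")
def effect_decoding(effect_preprocessed, config):
    binned, _, _ = effect_preprocessed
    return sd.loocv_decode(binned, config)


@pytest.fixture()
def random_binned(config):
    """Small label-balanced bin-power tensor with no category effect."""
    rng = np.random.default_rng(42)
    n_trials, n_channels = 12, 4
    power = rng.lognormal(mean=0.0, sigma=0.3, size=(n_trials, n_channels, config.n_bins))
    categories = np.asarray(["abstract", "concrete"] * (n_trials // 2), dtype=object)
    ids = tuple(f"ch{i}" for i in range(n_channels))
    return sd.BinnedPower(power=power, bin_edges_ms=config.bin_edges_ms,
                          categories=categories, channel_ids=ids)
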