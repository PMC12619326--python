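import numpy as np
import pytest

import serialdep as sd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_exp1_table():
    """A modest Experiment-1-style dataset with a planted 2-deg bias."""
    return sd.generate_experiment(
        sd.DesignSpec.exp1(n_participants=6, n_trials=240),
        profiles=sd.SDProfile(amplitude=2.0, width=35.0),
        noise=sd.NoiseSpec(response_sd=9.0),
        seed=42,
    )


@pytest.fixture(scope="session")
def null_exp1_table():
    """Bias-free, cardinal-free, outlier-free dataset."""
    return sd.generate_experiment(
        sd.DesignSpec.exp1(n_participants=6, n_trials=240),
        profiles=sd.SDProfile(amplitude=0.0, width=35.0),
        noise=sd.NoiseSpec(response_sd=9.0),
        seed=43,
        participant_amp_sd=0.0,
    )
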