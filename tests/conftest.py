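import numpy as np
import pytest

from myoforce.hill import HillParams, hill_force
from myoforce.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def true_params():
    return HillParams(W=0.22, v_max=8.0, A_rel=0.3, g_max=1.6, k_pee=5.0, l_slack_pee=1.05)


@pytest.fixture(scope="session")
def rich_trial(true_params):
    """Noiseless trial with rich (a, l, v) excitation from known parameters.

    Length sweeps well past the PEE slack and the force-length width;
    velocity reaches a few L0/s with active lengthening present, so all six
    parameters are identifiable.
    """
    fs = 500.0
    t = np.arange(0, 3.0, 1 / fs)
    lce = 1.0 + 0.2 * np.sin(2 * np.pi * 1.0 * t - np.pi / 2) + 0.12 * np.sin(2 * np.pi * 4.0 * t)
    vce = np.gradient(lce) * fs
    a = np.clip(0.55 + 0.45 * np.sin(2 * np.pi * 2.3 * t + 1.0), 0, None)
    f_max = 10.0
    force = hill_force(a, lce, vce, true_params, f_max)
    return {"a": a, "lce": lce, "vce": vce, "force": force, "f_max": f_max, "fs": fs}


@pytest.fixture(scope="session")
def small_config():
    """Small but complete synthetic grid (fast to generate and train on)."""
    return SyntheticConfig(
        n_birds=2,
        muscles=("LG", "DF"),
        speeds=(1.8, 4.5),
        obstacle_heights=(0, 7),
        fs=500.0,
        n_strides=6,
        history_gain=0.1,
        noise_sd_force=0.02,
        noise_sd_emg=0.01,
        activation_scale_error={("bird1", "DF"): 1.3, ("bird2", "DF"): 1.3},
        carrier_band=(80.0, 200.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
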