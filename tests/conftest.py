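import numpy as np
import pytest

from matefit import (
    FitConfig,
    NoiseModel,
    default_training_designs,
    fit_variant,
    generate_dataset,
    get_variant,
)

#: published best-fit kinetics of the selected six-parameter model, in its
#: free-vector order (psi_max_R, psi_max_D, K_L, gamma_max, e_R, e_D)
TABLE2_TRUTH = np.array([0.0571, 0.0392, 145.0, 1.27e-10, 6.22e-10, 1.86e-9])

#: published model-comparison ledger: variant -> (kinetic, m, SSE, AICc)
PUBLISHED_COMPARISON = {
    "V0": (19, 27, 416.1, 219.3),
    "V1": (16, 24, 420.7, 210.6),
    "V2": (11, 19, 420.7, 195.4),
    "V3": (10, 18, 420.7, 192.5),
    "V4": (9, 17, 495.5, 208.7),
    "V5": (9, 17, 420.7, 189.7),
    "V6": (8, 16, 420.8, 187.0),
    "V7": (7, 15, 420.8, 184.3),
    "V8": (6, 14, 471.1, 194.7),
    "V9": (6, 14, 514.8, 205.0),
    "V10": (6, 14, 514.9, 205.0),
    "V11": (6, 14, 577.0, 218.2),
    "V12": (6, 14, 490.1, 199.3),
    "V13": (4, 12, 651.8, 227.3),
    "V14": (2, 10, 700.1, 230.6),
    "V15": (6, 14, 420.8, 181.6),
}


@pytest.fixture(scope="session")
def v15():
    return get_variant("V15")


@pytest.fixture(scope="session")
def v14():
    return get_variant("V14")


@pytest.fixture(scope="session")
def training_designs():
    return default_training_designs()


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel(cv={"D": 0.0, "R": 0.0, "T": 0.0})


@pytest.fixture(scope="session")
def v15_noise_free_data(v15, training_designs, noiseless):
    """Noise-free triplicate dataset generated from the selected model at
    its published best-fit kinetics."""
    return generate_dataset(TABLE2_TRUTH, v15, training_designs, noiseless,
                            seed=11)


@pytest.fixture(scope="session")
def v15_noise_free_fit(v15, v15_noise_free_data):
    """Calibration of the selected model against its own noise-free data
    (shared across tests: the search is the expensive step)."""
    config = FitConfig(n_starts=12, seed=3, stop_sse=1e-4)
    return fit_variant(v15, v15_noise_free_data.observations, config)
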