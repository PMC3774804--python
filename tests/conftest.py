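import numpy as np
import pytest

import itkmaxent as im


@pytest.fixture(scope="session")
def specs():
    return {m: im.build_model(m) for m in im.MODEL_IDS}


@pytest.fixture(scope="session")
def calibration_init():
    return im.InitialState(Itk0=100, PIP3_0=370, PIP2_0=17000)


@pytest.fixture(scope="session")
def tight_sim():
    return im.SimulationConfig(rel_tol=1e-10, abs_tol=1e-12)


@pytest.fixture(scope="session")
def m3_calibrated_trajectory(specs, calibration_init, tight_sim):
    return im.integrate_ode(
        specs["M3"], im.base_parameters("M3"), calibration_init, tight_sim
    )


def random_positive_params(model_id: str, rng: np.random.Generator) -> im.ParameterSet:
    """A random positive parameter draw around the calibrated base values."""
    base = im.base_parameters(model_id)
    rates = {k: v * rng.uniform(0.1, 10.0) for k, v in base.rates.items()}
    alpha = None if base.alpha is None else float(rng.uniform(1.0, 4000.0))
    return im.ParameterSet(rates=rates, alpha=alpha)
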