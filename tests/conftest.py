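import numpy as np
import pytest

import thermodev as td


@pytest.fixture(scope="session")
def ler_params():
    """Development (leaf elongation) response with the measured parameters,
    unit amplitude."""
    return td.ResponseParams(A=1.0, dHa=69.1e3, alpha=3.5, T0=29.2 + 273.15)


@pytest.fixture(scope="session")
def gen_config():
    return td.GeneratorConfig()


@pytest.fixture(scope="session")
def grain_params_dev():
    """Paper-scale grain parameters in developmental time."""
    lam = td.lambda_from_ggrmax(1.18, td.W0_DEFAULT, td.T0_20_DEFAULT)
    return td.GrainGrowthParams(w0=td.W0_DEFAULT, t0=td.T0_20_DEFAULT,
                                lam=lam, time_basis="developmental")


def random_response_params(rng: np.random.Generator) -> td.ResponseParams:
    """Biologically plausible random response parameters."""
    return td.ResponseParams(
        A=float(np.exp(rng.uniform(0, 25))),
        dHa=float(rng.uniform(10e3, 150e3)),
        alpha=float(rng.uniform(1.0, 8.0)),
        T0=float(rng.uniform(295.0, 320.0)),
    )
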