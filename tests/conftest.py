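import math

import numpy as np
import pytest

from canolagsa import ParameterSpec, load_parameter_specs
from canolagsa.surrogate import Management, default_parameters, wuhan_weather

# closed-form Ishigami variance decomposition (a=7, b=0.1, U(-pi,pi)^3):
# V1 = (1 + b*pi^4/5)^2 / 2, V2 = a^2/8, V3 = 0, V13 = 8*b^2*pi^8/225
ISHIGAMI_A, ISHIGAMI_B = 7.0, 0.1
_V1 = 0.5 * (1 + ISHIGAMI_B * math.pi**4 / 5) ** 2
_V2 = ISHIGAMI_A**2 / 8
_V13 = 8 * ISHIGAMI_B**2 * math.pi**8 / 225
_V = _V1 + _V2 + _V13
ISHIGAMI_SI = {"x1": _V1 / _V, "x2": _V2 / _V, "x3": 0.0}
ISHIGAMI_STI = {"x1": (_V1 + _V13) / _V, "x2": _V2 / _V, "x3": _V13 / _V}


def ishigami_scalar(x1: float, x2: float, x3: float) -> float:
    return (
        math.sin(x1)
        + ISHIGAMI_A * math.sin(x2) ** 2
        + ISHIGAMI_B * x3**4 * math.sin(x1)
    )


@pytest.fixture(scope="session")
def ishigami_specs():
    return [ParameterSpec(f"x{i}", -math.pi, math.pi) for i in (1, 2, 3)]


@pytest.fixture(scope="session")
def ishigami_row_model():
    def model(p):
        return {"Y": ishigami_scalar(p["x1"], p["x2"], p["x3"])}

    return model


@pytest.fixture(scope="session")
def ishigami_array_model():
    def model(X):
        X = np.asarray(X)
        return (
            np.sin(X[:, 0])
            + ISHIGAMI_A * np.sin(X[:, 1]) ** 2
            + ISHIGAMI_B * X[:, 2] ** 4 * np.sin(X[:, 0])
        )

    return model


@pytest.fixture(scope="session")
def study_specs():
    return load_parameter_specs()


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def wuhan_season():
    """One deterministic synthetic Wuhan season plus its management."""
    return wuhan_weather(year=2018, seed=0)


@pytest.fixture(scope="session")
def wuhan_mgmt(wuhan_season) -> Management:
    return wuhan_season[1]
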