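import dataclasses

import numpy as np
import pytest

from monofilm import Isotherm, fixture_library, generate_isotherm


@pytest.fixture(scope="session")
def library():
    return fixture_library()


@pytest.fixture(scope="session")
def clean_isotherms(library):
    """Noise-free realizations of the bundled single-film fixtures."""
    out = {}
    for key, spec in library.items():
        if hasattr(spec, "a_lift"):
            out[key] = generate_isotherm(dataclasses.replace(spec, noise_sd_pi=0.0))
    return out


def make_linear_isotherm(a0=80.0, pi_max=40.0, n=400, label="linear"):
    """π = a0 − A on A ∈ [a0 − pi_max, a0]: closed-form A(π) = a0 − π."""
    area = np.linspace(a0, a0 - pi_max, n)
    pressure = a0 - area
    return Isotherm(area=area, pressure=pressure, label=label)


@pytest.fixture
def linear_isotherm():
    return make_linear_isotherm()
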