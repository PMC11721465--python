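import numpy as np
import pytest

from blimap.synthetic import AssayDesign, KineticParams, simulate_1to1_sensorgram


@pytest.fixture
def params_100nM() -> KineticParams:
    """K_D = 100 nM reference kinetics."""
    return KineticParams(k_on=1e5, k_off=1e-2, r_max=1.0)


@pytest.fixture
def series_62_1000nM() -> tuple[float, ...]:
    """Two-fold dilution series 62.5–1000 nM, in molar."""
    return (62.5e-9, 125e-9, 250e-9, 500e-9, 1000e-9)


@pytest.fixture
def quiet_design(series_62_1000nM) -> AssayDesign:
    """Noiseless, drift-free design long enough to approach plateau."""
    return AssayDesign(
        concentrations=series_62_1000nM,
        t_assoc=600.0,
        t_dissoc=300.0,
        sample_rate=2.0,
        seed=0,
    )


@pytest.fixture
def quiet_plate(params_100nM, quiet_design):
    return simulate_1to1_sensorgram(params_100nM, quiet_design, analyte="lig")


def closed_form_1to1(params: KineticParams, conc: float, t: np.ndarray) -> np.ndarray:
    """Independent closed-form association response used as a test oracle."""
    k_obs = params.k_on * conc + params.k_off
    r_eq = params.r_max * conc / (conc + params.k_off / params.k_on)
    return r_eq * (1.0 - np.exp(-k_obs * t))
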