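import numpy as np
import pytest

from indokin.kinetics import RateConstants, build_scheme
from indokin.spectra import build_default_library


@pytest.fixture(scope="session")
def water_library():
    return build_default_library("water")


@pytest.fixture(scope="session")
def ethanol_library():
    return build_default_library("ethanol")


@pytest.fixture(scope="session")
def water_scheme_268():
    return build_scheme("water", 268)


@pytest.fixture(scope="session")
def coarse_wavelengths():
    return np.linspace(320.0, 750.0, 40)


@pytest.fixture(scope="session")
def coarse_times():
    return np.geomspace(50e-15, 750e-12, 80)


def bare_rates(**kw) -> RateConstants:
    """All-zero rate set (T = 298.15 K) with selected fields overridden."""
    base = dict(k_LbLa=0.0, k_rad=0.0, k_ic=0.0, k_pair_f=0.0, k_pair_b=0.0,
                k_diss=0.0, k_gem=0.0, omega_escape=1.0, k_rec2=0.0, f_T=0.0,
                k_T=0.0, k_scav_H=0.0, k_scav_NO3=0.0, k_scav_pair_H=0.0,
                k_scav_pair_NO3=0.0, k_adduct=0.0, dE_sep=0.2, dE_pair=0.03,
                T=298.15)
    base.update(kw)
    return RateConstants(**base)
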