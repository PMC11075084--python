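"""Physical constants and the water viscosity table used for temperature rescaling."""

import numpy as np

#: hc in eV*nm (CODATA); photon_energy(lambda) = HC_EV_NM / lambda
HC_EV_NM = 1239.842

#: Boltzmann constant in eV/K
K_B_EV = 8.617333262e-5

# Dynamic viscosity of liquid water (mPa*s) on a 273.15-373.15 K grid, 5 K steps.
# Standard handbook values (IAPWS correlation, rounded to 4 digits); linearly
# interpolated, linearly extrapolated at the edges.
_VISC_T = np.arange(273.15, 373.15 + 1e-9, 5.0)
_VISC_ETA = np.array([
    1.7916, 1.5192, 1.3069, 1.1382, 1.0016, 0.8900, 0.7972, 0.7190,
    0.6527, 0.5961, 0.5465, 0.5036, 0.4660, 0.4329, 0.4035, 0.3774,
    0.3540, 0.3329, 0.3138, 0.2966, 0.2818,
])


def water_viscosity(T: float) -> float:
    """Dynamic viscosity of water in mPa*s at temperature ``T`` (K).

    Linear interpolation on the built-in 5 K table; linear extrapolation
    just outside 273.15-373.15 K so the 270-360 K contract of
    :func:`indokin.kinetics.temperature_rescale` is covered.
    """
    T = float(T)
    if T <= _VISC_T[0]:
        slope = (_VISC_ETA[1] - _VISC_ETA[0]) / (_VISC_T[1] - _VISC_T[0])
        return float(_VISC_ETA[0] + slope * (T - _VISC_T[0]))
    if T >= _VISC_T[-1]:
        slope = (_VISC_ETA[-1] - _VISC_ETA[-2]) / (_VISC_T[-1] - _VISC_T[-2])
        return float(_VISC_ETA[-1] + slope * (T - _VISC_T[-1]))
    return float(np.interp(T, _VISC_T, _VISC_ETA))


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy in eV of light with vacuum wavelength ``wavelength_nm``.

    >>> round(photon_energy(200.0), 2)
    6.2
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / float(wavelength_nm)
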