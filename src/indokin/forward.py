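"""Observables from concentration trajectories: TA matrices and TCSPC decays.

Transient absorption follows Beer-Lambert: each populated compartment
contributes its species spectrum weighted by population and the excited
molar concentration, the sum is convolved in time with a Gaussian
instrument response, and reported as dOD in mOD. Ground-state bleach and
stimulated emission are not modelled (the analysis regions are dominated by
excited-state/product absorption). TCSPC decays are the 1La radiative flux
convolved with the instrument response, multinomially sampled to a fixed
total photon count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._config import load_defaults
from .kinetics import ConcentrationMatrix, KineticScheme, propagate

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: kinetic compartment -> spectral species. H_atom and ground absorb nothing
#: in the probe window and are omitted.
STATE_SPECIES = {
    "Lb": "Lb_esa",
    "La": "La_esa",
    "pair": "e_pair",
    "e_sep": "e_separated",
    "cation": "cation",
    "triplet": "triplet",
    "adduct": "H_adduct",
}
_DARK_STATES = ("H_atom", "ground")


class MissingSpectrumError(KeyError):
    """A populated compartment has no spectrum in the supplied library."""


@dataclass(frozen=True)
class ExperimentGeometry:
    path_length: float        # cm
    c_exc: float              # excited molar concentration (M)
    irf_fwhm: float           # s
    time_zero: float = 0.0    # s; pump-probe overlap centre
    regime: str = "femto"     # "femto" or "nano"

    def __post_init__(self):
        if self.path_length <= 0 or self.c_exc <= 0 or self.irf_fwhm <= 0:
            raise ValueError("path_length, c_exc and irf_fwhm must be > 0")
        if self.regime not in ("femto", "nano"):
            raise ValueError(f"unknown regime {self.regime!r}")


def default_geometry(regime: str = "femto", excitation_nm: int = 268) -> ExperimentGeometry:
    """Shipped experiment geometry for the femto- or nanosecond instrument."""
    cfg = load_defaults()["geometry"][regime]
    irf = cfg["irf_fwhm_200"] if (regime == "femto" and excitation_nm == 200) else cfg["irf_fwhm"]
    return ExperimentGeometry(path_length=cfg["path_length"], c_exc=cfg["c_exc"],
                              irf_fwhm=irf, time_zero=cfg["time_zero"], regime=regime)


@dataclass
class TAMatrix:
    """dOD(wavelength, time) in mOD with grids, IRF descriptor and scatter mask.

    ``dod`` has shape (n_times, n_wavelengths); masked cells are NaN.
    """

    wavelengths: np.ndarray           # nm, ascending
    times: np.ndarray                 # s, ascending (may include pre-zero points)
    dod: np.ndarray                   # mOD
    irf_fwhm: float
    mask_intervals: list = field(default_factory=list)   # [(lo_nm, hi_nm), ...]

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, float)
        self.times = np.asarray(self.times, float)
        self.dod = np.asarray(self.dod, float)
        if self.dod.shape != (len(self.times), len(self.wavelengths)):
            raise ValueError("dod shape must be (n_times, n_wavelengths)")
        if np.any(np.diff(self.wavelengths) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("grids must be strictly ascending")

    def apply_mask(self, intervals) -> None:
        """NaN-out the listed wavelength intervals (pump-scatter windows)."""
        for lo, hi in intervals:
            sel = (self.wavelengths >= lo) & (self.wavelengths <= hi)
            self.dod[:, sel] = np.nan
            self.mask_intervals.append((float(lo), float(hi)))

    def trace(self, wavelength_nm: float) -> np.ndarray:
        """Kinetic trace at the grid wavelength closest to ``wavelength_nm``."""
        j = int(np.argmin(np.abs(self.wavelengths - wavelength_nm)))
        return self.dod[:, j]

    def spectrum_at(self, time_s: float) -> np.ndarray:
        """Spectral slice at the grid time closest to ``time_s``."""
        i = int(np.argmin(np.abs(self.times - time_s)))
        return self.dod[i, :]


def oversampled_times(times, irf_fwhm: float) -> np.ndarray:
    """Uniform internal grid (step = irf_fwhm / 10) covering ``times`` plus IRF padding.

    Starts no later than min(times, 0) - 6 sigma so the convolution sees the
    full pre-zero onset; ends 6 sigma past the last requested time.
    """
    times = np.asarray(times, float)
    sigma = irf_fwhm * _SIGMA_PER_FWHM
    step = irf_fwhm / 10.0
    lo = min(times[0], 0.0) - 6.0 * sigma
    hi = times[-1] + 6.0 * sigma
    n = int(np.ceil((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _populations_on(conc: ConcentrationMatrix, grid: np.ndarray) -> np.ndarray:
    """Per-state populations interpolated onto ``grid``; zero before t = 0."""
    out = np.zeros((len(grid), conc.populations.shape[1]))
    pos = grid >= conc.time_grid[0]
    for j in range(conc.populations.shape[1]):
        out[pos, j] = np.interp(grid[pos], conc.time_grid, conc.populations[:, j])
    return out


def simulate_ta(conc: ConcentrationMatrix, library: dict, geometry: ExperimentGeometry,
                wavelengths, times=None) -> TAMatrix:
    """Beer-Lambert TA surface from populations and species spectra.

    dOD(lambda, t) = 1000 * L * c_exc * sum_i eps_i(lambda, t - t_birth,i) * p_i(t),
    convolved along t with a Gaussian of ``geometry.irf_fwhm``. The solvation
    shift clock of each species starts at its first nonzero population.
    ``times`` are the reported delays (may include pre-zero points, which
    carry the IRF-broadened onset); they default to ``conc.time_grid``.
    ``conc`` should be sampled densely enough for linear interpolation onto
    the convolution grid and should span the requested window plus IRF
    padding (the synthetic-data generators guarantee this).
    """
    lam = np.asarray(wavelengths, float)
    out_times = np.asarray(conc.time_grid if times is None else times, float)
    grid = oversampled_times(out_times - geometry.time_zero, geometry.irf_fwhm)
    pops = _populations_on(conc, grid)
    scale = 1000.0 * geometry.path_length * geometry.c_exc

    signal = np.zeros((len(grid), len(lam)))
    for i, state in enumerate(conc.states):
        p = pops[:, i]
        if p.max() <= 1e-12:
            continue
        if state in _DARK_STATES:
            continue
        species = STATE_SPECIES.get(state)
        if species is None or species not in library:
            raise MissingSpectrumError(
                f"populated state {state!r} has no spectrum in the library")
        spec = library[species]
        birth = grid[int(np.argmax(p > 1e-12))]
        if spec.shift_amplitude == 0.0:
            signal += np.outer(p, spec.epsilon(lam, np.inf))
        else:
            t_rel = np.clip(grid - birth, 0.0, None)
            signal += p[:, None] * spec.epsilon(lam, t_rel)
    signal *= scale

    sigma_samples = geometry.irf_fwhm * _SIGMA_PER_FWHM / (grid[1] - grid[0])
    dod_uniform = gaussian_filter1d(signal, sigma_samples, axis=0, mode="constant", cval=0.0)

    dod = np.empty((len(out_times), len(lam)))
    for j in range(len(lam)):
        dod[:, j] = np.interp(out_times - geometry.time_zero, grid, dod_uniform[:, j])
    return TAMatrix(wavelengths=lam, times=out_times, dod=dod, irf_fwhm=geometry.irf_fwhm)


@dataclass
class TCSPCHistogram:
    """Photon-arrival histogram: channel centres (s) and integer (or expected) counts."""

    times: np.ndarray
    counts: np.ndarray
    channel_width: float
    irf_fwhm: float
    total_counts: int


def simulate_tcspc(scheme: KineticScheme, geometry: ExperimentGeometry,
                   n_channels: int, channel_width: float, total_counts: int,
                   seed: int | None = 0, sample: bool = True,
                   decay=None) -> TCSPCHistogram:
    """Simulate a TCSPC fluorescence histogram.

    The expected photon rate is proportional to k_rad * [1La](t) (or to a
    caller-supplied ``decay(t)`` law), convolved with the Gaussian IRF, and
    multinomially sampled to exactly ``total_counts`` photons. ``sample=False``
    returns the noiseless expectation normalized to the same total.
    """
    if total_counts < 1000:
        raise ValueError("total_counts must be >= 1000")
    if channel_width <= 0:
        raise ValueError("channel_width must be > 0")
    centers = (np.arange(n_channels) + 0.5) * channel_width
    t_excite = geometry.time_zero

    grid = oversampled_times(centers - t_excite, geometry.irf_fwhm)
    t_pos = np.clip(grid, 0.0, None)
    if decay is None:
        dense = np.unique(t_pos)
        conc = propagate(scheme, dense)
        la = np.interp(t_pos, conc.time_grid, conc.get("La"))
        rate = scheme.rates.k_rad * la
    else:
        rate = decay(t_pos)
    rate = np.where(grid >= 0, rate, 0.0)

    sigma_samples = geometry.irf_fwhm * _SIGMA_PER_FWHM / (grid[1] - grid[0])
    conv = gaussian_filter1d(rate, sigma_samples, mode="constant", cval=0.0)
    expected = np.interp(centers - t_excite, grid, conv)
    expected = np.clip(expected, 0.0, None)
    if expected.sum() <= 0:
        raise ValueError("expected decay has no intensity inside the window")
    p = expected / expected.sum()

    if sample:
        rng = np.random.default_rng(seed)
        counts = rng.multinomial(total_counts, p)
    else:
        counts = p * total_counts
    return TCSPCHistogram(times=centers, counts=counts, channel_width=channel_width,
                          irf_fwhm=geometry.irf_fwhm, total_counts=total_counts)
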