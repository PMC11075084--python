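"""Seeded generators of complete in-silico experiments with ground-truth sidecars.

These stand in for the study's raw data: femtosecond-regime TA matrices
(320-750 nm, 50 fs - 750 ps, Gaussian dOD noise, pump-scatter masks),
electron-scavenging kinetic series, and Poisson-count TCSPC histogram
series. Every dataset carries the generating scheme and geometry as a
``truth`` dict so that recovery can be benchmarked against it, and is
bitwise reproducible from its seed (per-trace substreams are derived from
the master seed by fixed offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._config import load_defaults
from . import forward as fwd
from .kinetics import Scavenger, build_scheme, propagate, scheme_to_dict

#: default Gaussian dOD noise floor, mOD (typical fs-TA; a stand-in)
DEFAULT_NOISE_SIGMA = 0.15


def default_wavelengths() -> np.ndarray:
    """120 probe wavelengths over 320-750 nm."""
    return np.linspace(320.0, 750.0, 120)


def default_times(regime: str = "femto") -> np.ndarray:
    """150 log-spaced delays 50 fs - 750 ps plus 5 pre-zero points (femto),
    or 200 log-spaced 5 ns - 100 us (nano)."""
    if regime == "nano":
        return np.geomspace(5e-9, 100e-6, 200)
    pre = np.array([-1.0, -0.75, -0.5, -0.25, -0.1]) * 1e-12
    return np.concatenate([pre, np.geomspace(50e-15, 750e-12, 150)])


@dataclass
class SyntheticDataset:
    ta: fwd.TAMatrix
    truth: dict
    noise_sigma: float
    seed: int


@dataclass
class ScavengingSeries:
    times: np.ndarray
    concentrations: np.ndarray
    traces: np.ndarray          # shape (n_conc, n_times), mOD
    probe_nm: float
    truth: dict
    noise_sigma: float
    seed: int


@dataclass
class TCSPCSeries:
    concentrations: np.ndarray
    histograms: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    seed: int = 0


def _scatter_mask(excitation_nm: int, scavenger) -> list:
    cfg = load_defaults()["masks"]
    if excitation_nm == 292:
        return [tuple(iv) for iv in cfg["nm_292"]]
    if excitation_nm == 268 and scavenger is not None and scavenger.species == "H+":
        return [tuple(iv) for iv in cfg["nm_268_H"]]
    return []


def generate_ta_dataset(solvent: str = "water", excitation_nm: int = 268,
                        scavenger=None, noise_sigma: float = DEFAULT_NOISE_SIGMA,
                        seed: int = 0, wavelengths=None, times=None,
                        regime: str = "femto") -> SyntheticDataset:
    """One complete synthetic TA experiment with Gaussian noise and scatter mask.

    ``scavenger`` is ``None``, a :class:`~indokin.kinetics.Scavenger`, or a
    ``{"species": ..., "concentration": ...}`` dict. The noiseless surface is
    the forward model exactly; noise is i.i.d. Gaussian with ``noise_sigma``
    mOD drawn from a stream derived from ``seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if scavenger is not None and not isinstance(scavenger, Scavenger):
        scavenger = Scavenger(**scavenger)
    if wavelengths is None:
        wavelengths = default_wavelengths()
    if times is None:
        times = default_times(regime)
    cfg = load_defaults()["geometry"]
    if regime == "nano":
        scheme = build_scheme(solvent, excitation_nm, scavenger,
                              c_exc=cfg["nano"]["c_exc"])
        geometry = fwd.default_geometry("nano")
    else:
        scheme = build_scheme(solvent, excitation_nm, scavenger)
        geometry = fwd.default_geometry("femto", excitation_nm)

    grid = fwd.oversampled_times(np.asarray(times) - geometry.time_zero, geometry.irf_fwhm)
    conc = propagate(scheme, grid[grid > 0])
    from .spectra import build_default_library
    lib = build_default_library(solvent)
    ta = fwd.simulate_ta(conc, lib, geometry, wavelengths, times=times)

    if noise_sigma > 0:
        rng = np.random.default_rng([int(seed), 101])
        ta.dod = ta.dod + rng.normal(0.0, noise_sigma, ta.dod.shape)
    ta.apply_mask(_scatter_mask(excitation_nm, scavenger))

    truth = {
        "scheme": scheme_to_dict(scheme),
        "geometry": {"path_length": geometry.path_length, "c_exc": geometry.c_exc,
                     "irf_fwhm": geometry.irf_fwhm, "time_zero": geometry.time_zero,
                     "regime": geometry.regime},
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
    }
    return SyntheticDataset(ta=ta, truth=truth, noise_sigma=noise_sigma, seed=int(seed))


def generate_scavenging_series(scavenger_species: str = "H+", concentrations=(0.0, 0.05, 0.1, 0.2),
                               probe_nm: float = 633.0,
                               noise_sigma: float = DEFAULT_NOISE_SIGMA, seed: int = 0,
                               solvent: str = "water", excitation_nm: int = 200,
                               times=None) -> ScavengingSeries:
    """Kinetic traces at one probe wavelength for a ladder of scavenger concentrations.

    Each concentration gets its own noise substream (fixed offsets from the
    master seed) so individual traces are reproducible. The truth records the
    bimolecular constant and the pseudo-first-order rates k * c it implies.
    """
    conc_list = np.asarray(list(concentrations), float)
    if len(conc_list) < 3:
        raise ValueError("need at least 3 concentrations for downstream regression")
    if np.any(conc_list < 0):
        raise ValueError("concentrations must be >= 0")
    if times is None:
        times = default_times("femto")
    times = np.asarray(times, float)
    geometry = fwd.default_geometry("femto", excitation_nm)
    from .spectra import build_default_library
    lib = build_default_library(solvent)

    traces = np.empty((len(conc_list), len(times)))
    scheme0 = None
    for i, c in enumerate(conc_list):
        scav = Scavenger(scavenger_species, float(c)) if c > 0 else None
        scheme = build_scheme(solvent, excitation_nm, scav)
        if scheme0 is None:
            scheme0 = scheme
        grid = fwd.oversampled_times(times - geometry.time_zero, geometry.irf_fwhm)
        cm = propagate(scheme, grid[grid > 0])
        ta = fwd.simulate_ta(cm, lib, geometry, [probe_nm], times=times)
        tr = ta.dod[:, 0]
        if noise_sigma > 0:
            rng = np.random.default_rng([int(seed), 301 + i])
            tr = tr + rng.normal(0.0, noise_sigma, tr.shape)
        traces[i] = tr

    rates = scheme0.rates
    k_bi = rates.k_scav_H if scavenger_species == "H+" else rates.k_scav_NO3
    truth = {
        "scheme": scheme_to_dict(scheme0),
        "scavenger_species": scavenger_species,
        "k_bimolecular": float(k_bi),
        "pseudo_first_order": [float(k_bi * c) for c in conc_list],
        "probe_nm": float(probe_nm),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
    }
    return ScavengingSeries(times=times, concentrations=conc_list, traces=traces,
                            probe_nm=probe_nm, truth=truth,
                            noise_sigma=noise_sigma, seed=int(seed))


def generate_tcspc_series(scavenger_species: str = "NO3-",
                          concentrations=(0.0, 0.1, 0.25, 0.5),
                          total_counts: int = 1_000_000, seed: int = 0,
                          solvent: str = "water", n_channels: int = 4096,
                          channel_width: float = 12.2e-12,
                          irf_fwhm: float = 1e-10,
                          sample: bool = True) -> TCSPCSeries:
    """TCSPC histograms for a ladder of quencher concentrations.

    Truth lifetimes follow the rate-additivity law
    1/tau(c) = 1/tau0 + k_scav_pair * c in water; in ethanol the quencher
    cannot reach the (absent) ion pair and the lifetime is invariant.
    """
    cfg = load_defaults()
    conc_list = np.asarray(list(concentrations), float)
    scheme = build_scheme(solvent, 268)
    if solvent == "ethanol":
        tau0 = cfg["calibration"]["tau_fl_ethanol"]
        k_pair_scav = 0.0
    else:
        tau0 = cfg["calibration"]["tau_fl_water"]
        k_pair_scav = (scheme.rates.k_scav_pair_H if scavenger_species == "H+"
                       else scheme.rates.k_scav_pair_NO3)
    lifetimes = 1.0 / (1.0 / tau0 + k_pair_scav * conc_list)

    geometry = fwd.ExperimentGeometry(path_length=1.0, c_exc=1e-6, irf_fwhm=irf_fwhm,
                                      time_zero=2e-9, regime="nano")
    hists = []
    for i, tau in enumerate(lifetimes):
        h = fwd.simulate_tcspc(scheme, geometry, n_channels, channel_width,
                               int(total_counts), seed=[int(seed), 501 + i],
                               sample=sample,
                               decay=lambda t, tau=tau: np.exp(-t / tau))
        hists.append(h)
    truth = {
        "tau0": float(tau0),
        "k_pair_scav": float(k_pair_scav),
        "lifetimes": [float(x) for x in lifetimes],
        "concentrations": [float(c) for c in conc_list],
        "seed": int(seed),
        "solvent": solvent,
    }
    return TCSPCSeries(concentrations=conc_list, histograms=hists, truth=truth,
                       seed=int(seed))
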