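"""Parameterized absorption spectra of the transient species.

Every transient observed in the visible probe window -- the separated
solvated electron, the contact-pair electron, the indole cation, the indolyl
radical, triplet indole, the 1La / 1Lb excited-state absorptions and the
H-atom adduct -- is represented as a sum of 1-3 Gaussian bands in wavelength.
The electron species additionally carry an exponential solvation blue-shift
(time constant ~1 ps): the band centre relaxes from its nascent position to
``center - shift_amplitude``.

Band parameters are qualitative digitizations of published transient spectra
(stored in ``defaults.toml``); they are shape stand-ins, adequate for kinetic
work where band *centres* matter but absolute amplitudes mostly cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._config import load_defaults

#: the full set of species identifiers known to the library
SPECIES_IDS = (
    "e_separated", "e_pair", "cation", "indolyl",
    "triplet", "La_esa", "Lb_esa", "H_adduct",
)

#: species absent in ethanol (no photoionization channel in that solvent)
IONIC_SPECIES = ("e_separated", "e_pair", "cation", "indolyl", "triplet", "H_adduct")

_FOUR_LN2 = 4.0 * math.log(2.0)


class UnknownSpeciesError(KeyError):
    """Raised when a species identifier is not part of the library."""


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band.

    Parameters
    ----------
    center : float
        Nascent band centre in nm (before any solvation shift).
    fwhm : float
        Full width at half maximum in nm.
    amplitude : float
        Molar absorptivity at the band centre, M^-1 cm^-1.
    """

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self):
        if not (200.0 <= self.center <= 1000.0):
            raise ValueError(f"band center {self.center} nm outside 200-1000 nm")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SpeciesSpectrum:
    """Wavelength- and time-dependent molar absorptivity of one species.

    ``shift_amplitude`` (nm, >= 0) and ``shift_tau`` (seconds) describe the
    solvation relaxation: every band centre moves as
    ``c(t) = c0 - shift_amplitude * (1 - exp(-t / shift_tau))``.
    """

    species_id: str
    bands: tuple[GaussianBand, ...] = field(default_factory=tuple)
    shift_amplitude: float = 0.0
    shift_tau: float = 1.0e-12

    def __post_init__(self):
        if self.species_id not in SPECIES_IDS:
            raise UnknownSpeciesError(self.species_id)
        if self.shift_amplitude < 0:
            raise ValueError("shift_amplitude must be >= 0")
        if self.shift_tau <= 0:
            raise ValueError("shift_tau must be > 0")
        object.__setattr__(self, "bands", tuple(self.bands))

    def band_centers(self, t: float) -> np.ndarray:
        """Band centres (nm) at time ``t`` seconds after species formation."""
        if t < 0:
            raise ValueError("time since formation must be >= 0")
        relax = self.shift_amplitude * (1.0 - math.exp(-t / self.shift_tau))
        return np.array([b.center - relax for b in self.bands])

    def epsilon(self, wavelength, t=np.inf):
        """Molar absorptivity (M^-1 cm^-1) at ``wavelength`` nm, ``t`` s after formation.

        ``wavelength`` may be a scalar or array. Values outside the 300-800 nm
        evaluation window are extrapolated by the same Gaussians (no clipping).
        """
        lam = np.asarray(wavelength, dtype=float)
        if np.isscalar(t) or np.ndim(t) == 0:
            centers = self.band_centers(float(t) if np.isfinite(t) else 1e3 * self.shift_tau + 1.0)
            out = np.zeros_like(lam, dtype=float)
            for band, c in zip(self.bands, centers):
                out = out + band.amplitude * np.exp(-_FOUR_LN2 * ((lam - c) / band.fwhm) ** 2)
            return out if out.ndim else float(out)
        # vectorized over time: returns array with shape t.shape + lam.shape
        tt = np.asarray(t, dtype=float)
        if np.any(tt < 0):
            raise ValueError("time since formation must be >= 0")
        relax = self.shift_amplitude * (1.0 - np.exp(-tt / self.shift_tau))
        out = np.zeros(tt.shape + lam.shape)
        for band in self.bands:
            c = band.center - relax
            out = out + band.amplitude * np.exp(
                -_FOUR_LN2 * ((lam[None, ...] - np.expand_dims(c, tuple(range(tt.ndim, tt.ndim + lam.ndim)))) / band.fwhm) ** 2
            )
        return out


def molar_absorptivity(spectrum: SpeciesSpectrum, wavelength: float, t: float) -> float:
    """Evaluate ``spectrum`` at ``wavelength`` (nm) and time-since-formation ``t`` (s)."""
    if t < 0:
        raise ValueError("time since formation must be >= 0")
    return spectrum.epsilon(wavelength, t)


def build_default_library(solvent: str = "water") -> dict[str, SpeciesSpectrum]:
    """Default species spectra for ``solvent`` ("water" or "ethanol").

    Water returns all eight species; ethanol returns only the parent
    excited-state absorptions (``La_esa``, ``Lb_esa``) because the
    photoionization channel is closed in that solvent.
    """
    if solvent not in ("water", "ethanol"):
        raise ValueError(f"unsupported solvent {solvent!r}")
    cfg = load_defaults()["spectra"]
    lib: dict[str, SpeciesSpectrum] = {}
    for sid in SPECIES_IDS:
        if solvent == "ethanol" and sid in IONIC_SPECIES:
            continue
        entry = cfg[sid]
        bands = tuple(GaussianBand(*row) for row in entry["bands"])
        lib[sid] = SpeciesSpectrum(
            species_id=sid,
            bands=bands,
            shift_amplitude=entry.get("shift_amplitude", 0.0),
            shift_tau=entry.get("shift_tau", 1.0e-12),
        )
    return lib


def library_to_csv(library: dict[str, SpeciesSpectrum], path, wavelengths=None,
                   t: float = np.inf) -> None:
    """Write sampled spectra as delimited text: ``wavelength_nm,<species_id>...``.

    Values are written with 6 significant digits; the tabulated form
    round-trips losslessly at that precision via :func:`library_from_csv`.
    """
    if wavelengths is None:
        wavelengths = np.arange(300.0, 800.0 + 1e-9, 2.0)
    lam = np.asarray(wavelengths, float)
    ids = list(library)
    cols = [library[s].epsilon(lam, t) for s in ids]
    with open(path, "w") as fh:
        fh.write("wavelength_nm," + ",".join(ids) + "\n")
        for i, w in enumerate(lam):
            fh.write(f"{w:.6g}," + ",".join(f"{col[i]:.6g}" for col in cols) + "\n")


def library_from_csv(path):
    """Read a sampled-spectrum table written by :func:`library_to_csv`.

    Returns ``(wavelengths, {species_id: epsilon_array})``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first column must be 'wavelength_nm'")
    lam = df["wavelength_nm"].to_numpy(float)
    return lam, {c: df[c].to_numpy(float) for c in df.columns[1:]}
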