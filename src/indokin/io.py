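"""File formats and configuration handling.

Everything the package writes is plain delimited text or TOML, and
everything it writes it can read back:

* TA matrices: first header cell literally ``time_ps\\wavelength_nm``,
  first row the probe wavelengths (nm), first column the delays (ps),
  cells dOD in mOD, masked cells the token ``NA``.
* TCSPC histograms: two columns ``time_ns,counts``.
* Kinetic-trace series: ``time_ps`` plus one labelled column per trace.
* Schemes, truth sidecars and run configs: TOML (read with stdlib
  ``tomllib``; written by the small serializer here).
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .forward import TAMatrix, TCSPCHistogram

TA_CORNER = "time_ps\\wavelength_nm"


class FormatError(ValueError):
    """A file does not follow the declared text format."""


# ---------------------------------------------------------------------------
# minimal TOML writer (tables, nested tables, scalars, lists)

def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if not math.isfinite(v):
            raise ValueError("non-finite floats are not serializable")
        s = repr(float(v))
        return s
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def toml_dumps(d: dict, _prefix: str = "") -> str:
    lines = []
    tables = []
    for k, v in d.items():
        if isinstance(v, dict):
            tables.append((k, v))
        else:
            lines.append(f"{k} = {_toml_scalar(v)}")
    out = "\n".join(lines)
    for k, v in tables:
        name = f"{_prefix}{k}"
        out += f"\n\n[{name}]\n" + toml_dumps(v, _prefix=name + ".").lstrip("\n")
    return out.lstrip("\n")


def toml_dump(d: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(toml_dumps(d) + "\n")


def toml_load(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


# ---------------------------------------------------------------------------
# TA matrix text format

def write_ta(ta: TAMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(TA_CORNER + "," + ",".join(f"{w:.6g}" for w in ta.wavelengths) + "\n")
        for i, t in enumerate(ta.times):
            cells = ("NA" if not np.isfinite(v) else f"{v:.6g}" for v in ta.dod[i])
            fh.write(f"{t * 1e12:.8g}," + ",".join(cells) + "\n")


def read_ta(path) -> TAMatrix:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    if header[0] != TA_CORNER:
        raise FormatError(
            f"first cell must be {TA_CORNER!r} (row 1, column 1), got {header[0]!r}")
    df = pd.read_csv(path, na_values=["NA"])
    wavelengths = np.array([float(w) for w in header[1:]])
    times = df.iloc[:, 0].to_numpy(float) * 1e-12
    dod = df.iloc[:, 1:].to_numpy(float)
    ta = TAMatrix(wavelengths=wavelengths, times=times, dod=dod, irf_fwhm=float("nan"))
    # reconstruct mask intervals from fully-NaN columns
    bad = np.all(~np.isfinite(dod), axis=0)
    i = 0
    while i < len(bad):
        if bad[i]:
            j = i
            while j + 1 < len(bad) and bad[j + 1]:
                j += 1
            ta.mask_intervals.append((float(wavelengths[i]), float(wavelengths[j])))
            i = j + 1
        else:
            i += 1
    return ta


# ---------------------------------------------------------------------------
# TCSPC and kinetic-trace formats

def write_tcspc(hist: TCSPCHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("time_ns,counts\n")
        for t, c in zip(hist.times, hist.counts):
            fh.write(f"{t * 1e9:.8g},{c:.10g}\n")


def read_tcspc(path):
    """Returns ``(times_s, counts)``."""
    df = pd.read_csv(path)
    if list(df.columns) != ["time_ns", "counts"]:
        raise FormatError("TCSPC files must have columns 'time_ns,counts'")
    return df["time_ns"].to_numpy(float) * 1e-9, df["counts"].to_numpy(float)


def write_traces(path, times_s, traces: dict) -> None:
    """Labelled kinetic traces: ``time_ps,<label>...``."""
    labels = list(traces)
    with open(path, "w") as fh:
        fh.write("time_ps," + ",".join(labels) + "\n")
        for i, t in enumerate(np.asarray(times_s, float)):
            fh.write(f"{t * 1e12:.8g}," +
                     ",".join(f"{traces[k][i]:.6g}" for k in labels) + "\n")


def read_traces(path):
    df = pd.read_csv(path)
    if df.columns[0] != "time_ps":
        raise FormatError("trace files must start with a 'time_ps' column")
    return (df["time_ps"].to_numpy(float) * 1e-12,
            {c: df[c].to_numpy(float) for c in df.columns[1:]})


# ---------------------------------------------------------------------------
# run configuration

_SCHEME_KEYS = {"solvent", "excitation_nm", "scavenger_species",
                "scavenger_concentration", "c_exc"}
_GEOMETRY_KEYS = {"regime", "path_length", "c_exc", "irf_fwhm", "time_zero"}
_GRID_KEYS = {"wavelength_min", "wavelength_max", "n_wavelengths",
              "time_min", "time_max", "n_times"}
_TOP_KEYS = {"scheme", "geometry", "grids", "seed", "noise_sigma", "output_dir",
             "rate_overrides"}


@dataclass
class RunConfig:
    """Validated simulation configuration (defaults < config file < CLI flags)."""

    scheme: dict = dc_field(default_factory=dict)
    geometry: dict = dc_field(default_factory=dict)
    grids: dict = dc_field(default_factory=dict)
    rate_overrides: dict = dc_field(default_factory=dict)
    seed: int = 0
    noise_sigma: float = 0.15
    output_dir: str = "."


def load_run_config(path) -> RunConfig:
    raw = toml_load(path)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise FormatError(f"unknown config key {sorted(unknown)[0]!r}")
    for section, allowed in (("scheme", _SCHEME_KEYS), ("geometry", _GEOMETRY_KEYS),
                             ("grids", _GRID_KEYS)):
        extra = set(raw.get(section, {})) - allowed
        if extra:
            raise FormatError(f"unknown config key {section}.{sorted(extra)[0]}")
    sc = raw.get("scheme", {})
    if sc.get("scavenger_concentration", 0) < 0:
        raise FormatError("scheme.scavenger_concentration must be >= 0")
    if "excitation_nm" in sc and sc["excitation_nm"] not in (200, 268, 292):
        raise FormatError("scheme.excitation_nm must be one of 200, 268, 292")
    if "solvent" in sc and sc["solvent"] not in ("water", "ethanol"):
        raise FormatError("scheme.solvent must be 'water' or 'ethanol'")
    return RunConfig(
        scheme=sc, geometry=raw.get("geometry", {}), grids=raw.get("grids", {}),
        rate_overrides=raw.get("rate_overrides", {}),
        seed=int(raw.get("seed", 0)), noise_sigma=float(raw.get("noise_sigma", 0.15)),
        output_dir=str(raw.get("output_dir", ".")),
    )
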