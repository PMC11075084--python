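"""The photoionization mechanism of aqueous indole as a compartment kinetic model.

Nine compartments: the two singlet excited states (1Lb, 1La), the contact
ion pair 1[Ind+:e-] in dynamic equilibrium with 1La, separated solvated
electrons and indole cations produced by pair dissociation, triplet indole
formed on free-ion recombination (radical-pair intersystem crossing),
H atoms from proton scavenging, the H-atom/cation adduct, and the ground
state. 268/292 nm excitation enters through the singlet manifold; 200 nm
excitation additionally ejects electrons ballistically into the solvent
(prompt ionization) with escape-fraction geminate recombination. Ethanol
supports no ionization: the singlet manifold simply decays.

Population bookkeeping is indole-centred: the fractions in
``CONSERVED_STATES`` sum to one per absorbed photon. ``e_sep`` and
``H_atom`` are electron-side species that mirror the cation bookkeeping and
are excluded from that sum (a separated electron and its geminate cation
derive from the same photon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict, fields as dc_fields
from functools import lru_cache

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ._config import load_defaults
from .constants import K_B_EV, photon_energy, water_viscosity  # noqa: F401 (re-export)

STATES = ("Lb", "La", "pair", "e_sep", "cation", "triplet", "H_atom", "adduct", "ground")
#: indole-centred compartments whose populations sum to 1 per absorbed photon
CONSERVED_STATES = ("Lb", "La", "pair", "cation", "triplet", "adduct", "ground")

_IDX = {s: i for i, s in enumerate(STATES)}


class IntegrationError(RuntimeError):
    """Stiff-integration failure; carries the failing time in ``.t_fail``."""

    def __init__(self, message, t_fail=None):
        super().__init__(message)
        self.t_fail = t_fail


@dataclass(frozen=True)
class RateConstants:
    """Rate constants and thermodynamic parameters of the mechanism.

    Unimolecular rates in s^-1, bimolecular in M^-1 s^-1, energies in eV,
    temperature in K. ``omega_escape`` and ``f_T`` are dimensionless
    branching fractions.
    """

    k_LbLa: float
    k_rad: float
    k_ic: float
    k_pair_f: float
    k_pair_b: float
    k_diss: float
    k_gem: float
    omega_escape: float
    k_rec2: float
    f_T: float
    k_T: float
    k_scav_H: float
    k_scav_NO3: float
    k_scav_pair_H: float
    k_scav_pair_NO3: float
    k_adduct: float
    dE_sep: float
    dE_pair: float
    T: float

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if f.name in ("dE_sep", "dE_pair"):
                continue
            if f.name == "T":
                if v <= 0:
                    raise ValueError("temperature must be > 0")
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if not 0 <= self.omega_escape <= 1:
            raise ValueError("omega_escape must lie in [0, 1]")
        if not 0 <= self.f_T <= 1:
            raise ValueError("f_T must lie in [0, 1]")


@dataclass(frozen=True)
class Scavenger:
    species: str              # "H+" or "NO3-"
    concentration: float      # M

    def __post_init__(self):
        if self.species not in ("H+", "NO3-"):
            raise ValueError(f"unknown scavenger species {self.species!r}")
        if self.concentration < 0:
            raise ValueError("scavenger concentration must be >= 0")


@dataclass(frozen=True)
class KineticScheme:
    """A fully specified experiment-ready mechanism (the Figure-6 scheme as data)."""

    rates: RateConstants
    solvent: str
    excitation_nm: int
    scavenger: Scavenger | None
    initial_conditions: dict[str, float]
    c_exc: float              # excited-state molar concentration scale (M)

    def __post_init__(self):
        total = sum(self.initial_conditions.get(s, 0.0) for s in CONSERVED_STATES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial indole populations sum to {total}, not 1")
        if self.c_exc <= 0:
            raise ValueError("c_exc must be > 0")

    def initial_vector(self) -> np.ndarray:
        y0 = np.zeros(len(STATES))
        for s, v in self.initial_conditions.items():
            y0[_IDX[s]] = v
        return y0


@dataclass
class ConcentrationMatrix:
    """Per-photon populations of every compartment on a time grid."""

    time_grid: np.ndarray     # s, strictly increasing
    states: tuple[str, ...]
    populations: np.ndarray   # shape (n_times, n_states), clipped to >= 0
    c_exc: float              # molar scale: concentration = c_exc * population

    def get(self, state: str) -> np.ndarray:
        return self.populations[:, self.states.index(state)]

    def conservation_defect(self) -> float:
        """Max deviation of the indole-ledger population sum from 1."""
        cols = [self.states.index(s) for s in CONSERVED_STATES]
        return float(np.abs(self.populations[:, cols].sum(axis=1) - 1.0).max())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s," + ",".join(self.states) + "\n")
            for i, t in enumerate(self.time_grid):
                fh.write(f"{t:.9e}," + ",".join(f"{v:.9e}" for v in self.populations[i]) + "\n")


def _scav_rates(rates: RateConstants, scavenger: Scavenger | None):
    """Pseudo-first-order scavenging rates (separated electron, pair electron)."""
    if scavenger is None or scavenger.concentration == 0:
        return 0.0, 0.0, False
    c = scavenger.concentration
    if scavenger.species == "H+":
        return rates.k_scav_H * c, rates.k_scav_pair_H * c, True
    return rates.k_scav_NO3 * c, rates.k_scav_pair_NO3 * c, False


def geminate_survival(rates: RateConstants, t):
    """Pair-survival S(t) = omega + (1 - omega) exp(-k_gem t) for 200 nm-born charges."""
    w = rates.omega_escape
    return w + (1.0 - w) * np.exp(-rates.k_gem * np.asarray(t, float))


def _geminate_rate(rates: RateConstants, t: float) -> float:
    """Instantaneous first-order loss -S'(t)/S(t) of 200 nm-born charge pairs."""
    w = rates.omega_escape
    e = math.exp(-rates.k_gem * t) if rates.k_gem * t < 700 else 0.0
    s = w + (1.0 - w) * e
    return (1.0 - w) * rates.k_gem * e / s if s > 0 else 0.0


def _rhs_factory(scheme: KineticScheme):
    r = scheme.rates
    k_se, k_sp, makes_H = _scav_rates(r, scheme.scavenger)
    geminate = scheme.solvent == "water" and scheme.excitation_nm == 200
    c_exc = scheme.c_exc

    def rhs(t, y):
        Lb, La, pair, e, cat, T3, H, add, gnd = y
        r_Lb = r.k_LbLa * Lb
        r_rad = r.k_rad * La
        r_ic = r.k_ic * La
        r_pf = r.k_pair_f * La
        r_pb = r.k_pair_b * pair
        r_diss = r.k_diss * pair
        r_pscav = k_sp * pair
        r_escav = k_se * e
        r_rec = r.k_rec2 * c_exc * e * cat
        r_gem = _geminate_rate(r, t) * min(e, cat) if geminate else 0.0
        r_add = r.k_adduct * c_exc * H * cat
        r_T = r.k_T * T3
        dLb = -r_Lb
        dLa = r_Lb + r_pb - r_rad - r_ic - r_pf
        dpair = r_pf - r_pb - r_diss - r_pscav
        de = r_diss - r_escav - r_rec - r_gem
        dcat = r_diss + r_pscav - r_rec - r_gem - r_add
        dT = r.f_T * (r_rec + r_gem) - r_T
        dH = (r_escav + r_pscav if makes_H else 0.0) - r_add
        dadd = r_add
        dgnd = r_rad + r_ic + (1.0 - r.f_T) * (r_rec + r_gem) + r_T
        return (dLb, dLa, dpair, de, dcat, dT, dH, dadd, dgnd)

    return rhs


def propagate(scheme: KineticScheme, time_grid) -> ConcentrationMatrix:
    """Integrate the coupled first-order system onto ``time_grid`` (s).

    A stiff-capable implicit solver (LSODA) with rtol 1e-8 / atol 1e-12;
    integration always starts at t = 0 where the initial conditions are
    defined. Output populations are clipped at zero (tolerance -1e-12).
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("time_grid must be a non-empty 1-D array")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if t[0] < 0:
        raise ValueError("time_grid must start at >= 0")
    y0 = scheme.initial_vector()
    t_eval = t if t[0] > 0 else t
    sol = solve_ivp(
        _rhs_factory(scheme), (0.0, float(t[-1])), y0, t_eval=t_eval,
        method="LSODA", rtol=1e-8, atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(f"stiff integration failed: {sol.message}",
                               t_fail=sol.t[-1] if len(sol.t) else 0.0)
    pops = sol.y.T
    if pops.min() < -1e-9:
        raise IntegrationError(f"negative population {pops.min():.3e}")
    return ConcentrationMatrix(time_grid=t, states=STATES,
                               populations=np.clip(pops, 0.0, None), c_exc=scheme.c_exc)


def analytic_equilibrium_drain(k_pair_f, k_pair_b, k_diss, t):
    """Exact biexponential solution of La <-> pair -> (drain), La(0) = 1.

    Returns ``(La(t), pair(t))``; the closed-form oracle for :func:`propagate`
    on the two-state sub-scheme.
    """
    if min(k_pair_f, k_pair_b, k_diss) < 0:
        raise ValueError("rates must be >= 0")
    t = np.asarray(t, dtype=float)
    a = k_pair_f
    b = k_pair_b + k_diss
    # eigenvalues of the decay matrix [[a, -k_pair_b], [-k_pair_f, b]]
    s = 0.5 * (a + b)
    d = math.sqrt(0.25 * (a - b) ** 2 + k_pair_f * k_pair_b)
    lam1, lam2 = s - d, s + d  # slow, fast
    if d < 1e-12 * max(s, 1.0):  # degenerate pair: defective only if kf*kb = 0
        La = np.exp(-a * t)
        pair = k_pair_f * t * np.exp(-a * t)
        return La, pair
    # La(t) = c1 e^{-lam1 t} + c2 e^{-lam2 t} with La(0)=1, La'(0) = -a
    c1 = (lam2 - a) / (lam2 - lam1)
    c2 = 1.0 - c1
    e1 = np.exp(-lam1 * t)
    e2 = np.exp(-lam2 * t)
    La = c1 * e1 + c2 * e2
    pair = (k_pair_f / (lam2 - lam1)) * (e1 - e2)
    return La, pair


def drain_eigenvalues(k_pair_f, k_pair_b, k_diss):
    """(slow, fast) decay eigenvalues of the La <-> pair -> drain sub-scheme."""
    a = k_pair_f
    b = k_pair_b + k_diss
    s = 0.5 * (a + b)
    d = math.sqrt(0.25 * (a - b) ** 2 + k_pair_f * k_pair_b)
    return s - d, s + d


def effective_fluorescence_lifetime(scheme: KineticScheme) -> float:
    """Reciprocal of the slowest decay eigenvalue of the {1La, pair} subsystem.

    Includes radiative and internal-conversion decay, the pair equilibrium
    and its dissociation drain, and pseudo-first-order scavenging of the
    pair-bound electron.
    """
    r = scheme.rates
    _, k_sp, _ = _scav_rates(r, scheme.scavenger)
    a = r.k_rad + r.k_ic + r.k_pair_f
    b = r.k_pair_b + r.k_diss + k_sp
    if a == 0 and b == 0:
        raise ValueError("degenerate (all-zero) {La, pair} subsystem")
    if r.k_pair_f == 0:
        if a == 0:
            raise ValueError("1La has no decay channel")
        return 1.0 / a
    s = 0.5 * (a + b)
    d = math.sqrt(0.25 * (a - b) ** 2 + r.k_pair_f * r.k_pair_b)
    lam_slow = s - d
    if lam_slow <= 0:
        raise ValueError("subsystem has no decaying slow mode")
    return 1.0 / lam_slow


def temperature_rescale(rates: RateConstants, T_new: float) -> RateConstants:
    """Rescale the default-temperature rate set to ``T_new`` (K).

    The pair equilibrium constant K = k_pair_f/k_pair_b follows van't Hoff
    with the pair endothermicity dE_pair (applied to k_pair_f). Pair
    dissociation carries an Arrhenius factor with activation energy
    (dE_sep - dE_pair) -- the remaining uphill step from the pair to the
    separated ions -- times the Stokes-Einstein diffusional factor
    (T/eta ratio), so the composite K * k_diss scales with the full
    separated-ion endothermicity dE_sep. All diffusion-limited bimolecular
    rates scale with T/eta alone. Everything else is unchanged.
    """
    if not (270.0 <= T_new <= 360.0):
        raise ValueError(f"T_new = {T_new} K outside the supported 270-360 K range")
    T0 = rates.T
    if T_new == T0:
        return rates
    inv_diff = 1.0 / T0 - 1.0 / T_new   # > 0 when heating
    vh_pair = math.exp((rates.dE_pair / K_B_EV) * inv_diff)
    arr_diss = math.exp(((rates.dE_sep - rates.dE_pair) / K_B_EV) * inv_diff)
    visc = (T_new / T0) * (water_viscosity(T0) / water_viscosity(T_new))
    return replace(
        rates,
        k_pair_f=rates.k_pair_f * vh_pair,
        k_diss=rates.k_diss * arr_diss * visc,
        k_rec2=rates.k_rec2 * visc,
        k_scav_H=rates.k_scav_H * visc,
        k_scav_NO3=rates.k_scav_NO3 * visc,
        k_scav_pair_H=rates.k_scav_pair_H * visc,
        k_scav_pair_NO3=rates.k_scav_pair_NO3 * visc,
        k_adduct=rates.k_adduct * visc,
        T=T_new,
    )


# ---------------------------------------------------------------------------
# default parameter set and its build-time calibration

def _water_rates_for(k_diss: float, cfg: dict) -> RateConstants:
    """Water rate set with k_ic chosen so the slow {La, pair} eigenvalue is 1/tau_fl."""
    cal = cfg["calibration"]
    r = cfg["rates"]
    lam_s = 1.0 / cal["tau_fl_water"]
    k_pair_b = r["k_pair_b"]
    k_pair_f = cal["K_pair"] * k_pair_b
    b = k_pair_b + k_diss
    a = lam_s + k_pair_f * k_pair_b / (b - lam_s)
    k_ic = a - r["k_rad"] - k_pair_f
    if k_ic < 0:
        raise ValueError(f"k_diss = {k_diss:.4g} requires negative k_ic")
    return RateConstants(
        k_LbLa=r["k_LbLa"], k_rad=r["k_rad"], k_ic=k_ic,
        k_pair_f=k_pair_f, k_pair_b=k_pair_b, k_diss=k_diss,
        k_gem=r["k_gem"], omega_escape=r["omega_escape"], k_rec2=r["k_rec2"],
        f_T=r["f_T"], k_T=r["k_T"], k_scav_H=r["k_scav_H"],
        k_scav_NO3=r["k_scav_NO3"], k_scav_pair_H=r["k_scav_pair_H"],
        k_scav_pair_NO3=r["k_scav_pair_NO3"], k_adduct=r["k_adduct"],
        dE_sep=r["dE_sep"], dE_pair=r["dE_pair"], T=r["T"],
    )


def _electron_yield(rates: RateConstants, cfg: dict) -> float:
    """Surviving separated-electron fraction at the calibration horizon (268 nm)."""
    cal = cfg["calibration"]
    scheme = KineticScheme(
        rates=rates, solvent="water", excitation_nm=268, scavenger=None,
        initial_conditions={"La": cfg["initial"]["frac_La_268"],
                            "Lb": 1.0 - cfg["initial"]["frac_La_268"]},
        c_exc=cfg["geometry"]["femto"]["c_exc"],
    )
    grid = np.geomspace(1e-14, cal["horizon"], 400)
    conc = propagate(scheme, grid)
    return float(conc.get("e_sep")[-1])


@lru_cache(maxsize=4)
def default_rate_constants(solvent: str = "water") -> RateConstants:
    """The shipped default rate set, finalized at build time.

    For water, ``k_diss`` and ``k_ic`` are solved so that (a) the slow decay
    eigenvalue of the {1La, pair} subsystem equals 1/tau_fl_water and
    (b) the separated-electron yield per absorbed photon at the 1 us horizon
    (free-ion recombination active, default excitation concentration)
    equals the configured phi_electron. For ethanol the ionization channel
    is closed and k_ic is set from tau_fl_ethanol.
    """
    cfg = load_defaults()
    cal = cfg["calibration"]
    if solvent == "ethanol":
        base = _water_rates_for(1e8, cfg)  # template; ionic rates then zeroed
        k_ic = 1.0 / cal["tau_fl_ethanol"] - cfg["rates"]["k_rad"]
        return replace(base, k_ic=k_ic, k_pair_f=0.0, k_diss=0.0,
                       k_gem=0.0, omega_escape=1.0, k_rec2=0.0,
                       k_scav_H=0.0, k_scav_NO3=0.0,
                       k_scav_pair_H=0.0, k_scav_pair_NO3=0.0, k_adduct=0.0)
    if solvent != "water":
        raise ValueError(f"unsupported solvent {solvent!r}")

    lam_s = 1.0 / cal["tau_fl_water"]
    k_pair_b = cfg["rates"]["k_pair_b"]
    k_pair_f = cal["K_pair"] * k_pair_b
    # k_ic >= 0 bounds the admissible k_diss from above
    k_diss_max = k_pair_f * k_pair_b / (cfg["rates"]["k_rad"] + k_pair_f - lam_s) \
        - k_pair_b + lam_s

    def defect(k_diss):
        return _electron_yield(_water_rates_for(k_diss, cfg), cfg) - cal["phi_electron"]

    k_diss = brentq(defect, 1e7, 0.999 * k_diss_max, xtol=1e-3, rtol=1e-10)
    return _water_rates_for(k_diss, cfg)


def build_scheme(solvent: str = "water", excitation_nm: int = 268,
                 scavenger=None, overrides: dict | None = None,
                 c_exc: float | None = None) -> KineticScheme:
    """Assemble a :class:`KineticScheme` for the requested experiment.

    268 nm excitation populates 1La:1Lb = 3:1; 292 nm populates them equally;
    200 nm in water sends a fraction phi_prompt directly into separated
    electron/cation pairs and the remainder into hot 1Lb. Ethanol supports
    no ionic chemistry at any wavelength.
    """
    cfg = load_defaults()
    if solvent not in ("water", "ethanol"):
        raise ValueError(f"unknown solvent {solvent!r}")
    if excitation_nm not in (200, 268, 292):
        raise ValueError(f"unsupported excitation wavelength {excitation_nm} nm")
    if scavenger is not None and not isinstance(scavenger, Scavenger):
        scavenger = Scavenger(**scavenger)

    rates = default_rate_constants(solvent)
    if overrides:
        unknown = set(overrides) - {f.name for f in dc_fields(RateConstants)}
        if unknown:
            raise ValueError(f"unknown rate override(s): {sorted(unknown)}")
        rates = replace(rates, **overrides)

    if solvent == "ethanol":
        if excitation_nm == 200:
            init = {"Lb": 1.0}
        else:
            f_la = cfg["initial"][f"frac_La_{excitation_nm}"]
            init = {"La": f_la, "Lb": 1.0 - f_la}
    elif excitation_nm == 200:
        phi = cfg["calibration"]["phi_prompt_200"]
        init = {"e_sep": phi, "cation": phi, "Lb": 1.0 - phi}
    else:
        f_la = cfg["initial"][f"frac_La_{excitation_nm}"]
        init = {"La": f_la, "Lb": 1.0 - f_la}

    if c_exc is None:
        c_exc = cfg["geometry"]["femto"]["c_exc"]
    return KineticScheme(rates=rates, solvent=solvent, excitation_nm=excitation_nm,
                         scavenger=scavenger, initial_conditions=init, c_exc=c_exc)


def nanosecond_scheme(scavenger=None, overrides=None) -> KineticScheme:
    """Default scheme for the nanosecond-regime (5 ns pulse, 266/268 nm) experiment."""
    cfg = load_defaults()
    return build_scheme("water", 268, scavenger=scavenger, overrides=overrides,
                        c_exc=cfg["geometry"]["nano"]["c_exc"])


def scheme_to_dict(scheme: KineticScheme) -> dict:
    """Plain-dict form of a scheme (TOML-serializable, keys = field names)."""
    d = {
        "solvent": scheme.solvent,
        "excitation_nm": scheme.excitation_nm,
        "c_exc": scheme.c_exc,
        "initial_conditions": dict(scheme.initial_conditions),
        "rates": asdict(scheme.rates),
    }
    if scheme.scavenger is not None:
        d["scavenger"] = {"species": scheme.scavenger.species,
                          "concentration": scheme.scavenger.concentration}
    return d


def scheme_from_dict(d: dict) -> KineticScheme:
    scav = d.get("scavenger")
    return KineticScheme(
        rates=RateConstants(**d["rates"]),
        solvent=d["solvent"],
        excitation_nm=int(d["excitation_nm"]),
        scavenger=Scavenger(**scav) if scav else None,
        initial_conditions=dict(d["initial_conditions"]),
        c_exc=float(d["c_exc"]),
    )
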