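"""Osmotic-actuator simulator: free-piston and bulging-disk turgor modes.

The actuation chamber (initial volume ``V_0``) holds the osmolyte solution and
exchanges water with an infinite pure-water reservoir across a semi-permeable
membrane.  Transport follows a Kedem-Katchalsky-style law:

    dV/dt   = S_OM * alpha_OM * (sum_i sigma_i * R*T * c_i  -  P)
    dN_i/dt = -P_s,i * S_OM * c_i  -  (1 - sigma_i) * c_i * dV/dt

with ``P = k_BD * (V - V_0) / V_0`` in turgor mode (linear elastic bulging
disk) and ``P = 0`` in piston mode.  KCl is tracked as separate K+ and Cl-
ions, so its dissociation count enters through the particle bookkeeping; the
driving force uses ideal particle concentrations (the cryoscopic gamma
corrections belong to the osmometry estimator, not to membrane transport).

With an optional :class:`~turgorkit.association.ComplexModel` coupling, the
chamber contents are re-speciated at every step: complexes are fully rejected
(sigma = 1, P_s = 0) and only free species leak, which expresses the
size-exclusion argument for the cooperative mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .association import COMPLEX_MEMBERS, ComplexModel, speciate
from .mixtures import MixtureComposition, OsmoticModelParams

__all__ = [
    "DEFAULT_SIGMA",
    "DEFAULT_P_S",
    "DEFAULT_V0",
    "DEFAULT_S_OM",
    "DEFAULT_ALPHA_OM",
    "DEFAULT_K_BD",
    "DEFAULT_P_REF",
    "MembraneSpec",
    "ActuatorConfig",
    "TurgorTrace",
    "chamber_species",
    "simulate",
    "simulate_fixed_step",
    "equilibrium_pressure",
    "characteristic_time",
    "characteristic_time_numeric",
    "nondimensionalize",
]

#: Reflection coefficients: salt ions at the midpoint of the 50-70% rejection
#: range, near-total rejection for the sugar and the amino acid.
DEFAULT_SIGMA: dict[str, float] = {"K+": 0.6, "Cl-": 0.6, "D-Glc": 0.99, "L-Gln": 1.0}

#: Diffusive solute permeabilities (m/s).  The ion value is set so that salt
#: backflow is visible within a few characteristic times of the device; the
#: retained solutes leak negligibly.
DEFAULT_P_S: dict[str, float] = {"K+": 5e-5, "Cl-": 5e-5, "D-Glc": 1e-9, "L-Gln": 0.0}

DEFAULT_V0 = 3e-6        # m^3, chamber volume at the ~10 mm device lengthscale
DEFAULT_S_OM = 1e-4      # m^2, membrane area
DEFAULT_ALPHA_OM = 3e-13  # m s^-1 Pa^-1, membrane water permeability
DEFAULT_P_REF = 1e5      # Pa, reference pressure defining the actuation time

#: Bulging-disk stiffness (Pa per unit relative volume change), back-solved so
#: the 1.5 M salt reference pressurizes on a one-minute characteristic time.
DEFAULT_K_BD = DEFAULT_P_REF * DEFAULT_V0 / (
    DEFAULT_S_OM * DEFAULT_ALPHA_OM * 60.0 * 0.6 * 6.37e6
)


@dataclass(frozen=True)
class MembraneSpec:
    """Semi-permeable membrane: area, water permeability, per-solute leak."""

    S_OM: float = DEFAULT_S_OM
    alpha_OM: float = DEFAULT_ALPHA_OM
    sigma: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    P_s: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_P_S))
    pore_size_nm: tuple[float, float] = (0.3, 0.5)

    def __post_init__(self) -> None:
        if self.S_OM <= 0 or self.alpha_OM <= 0:
            raise ValueError("S_OM and alpha_OM must be positive")
        for sp, s in self.sigma.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sigma[{sp}] must be in [0, 1]")
        for sp, p in self.P_s.items():
            if p < 0:
                raise ValueError(f"P_s[{sp}] must be >= 0")


@dataclass(frozen=True)
class ActuatorConfig:
    """Device configuration for one simulation run."""

    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    V_0: float = DEFAULT_V0
    k_BD: float = DEFAULT_K_BD
    mode: str = "turgor"
    P_ref: float = DEFAULT_P_REF
    coupling: Optional[ComplexModel] = None
    piston_area: float = 1e-3  # m^2

    def __post_init__(self) -> None:
        if self.mode not in ("piston", "turgor"):
            raise ValueError(f"mode must be 'piston' or 'turgor', got {self.mode!r}")
        if self.V_0 <= 0:
            raise ValueError("V_0 must be positive")
        if self.mode == "turgor" and self.k_BD <= 0:
            raise ValueError("k_BD must be positive in turgor mode")
        if self.P_ref <= 0:
            raise ValueError("P_ref must be positive")


@dataclass
class TurgorTrace:
    """Sampled time series of a simulation run (SI units)."""

    time: np.ndarray                 # s (or t/t_s after nondimensionalization)
    volume: np.ndarray               # m^3
    pressure: np.ndarray             # Pa
    chamber_amounts: dict[str, np.ndarray]  # mol per tracked species
    pi_internal: np.ndarray          # Pa, ideal internal osmotic potential
    t_over_ts: Optional[np.ndarray] = None


def chamber_species(mix: MixtureComposition) -> dict[str, float]:
    """Tracked chamber species and molarities (mol/L); KCl splits into ions."""
    out: dict[str, float] = {}
    for sp, molarity in mix.species_molarity.items():
        if sp == "KCl":
            out["K+"] = out.get("K+", 0.0) + molarity
            out["Cl-"] = out.get("Cl-", 0.0) + molarity
        else:
            out[sp] = out.get(sp, 0.0) + molarity
    return out


def _build_problem(config: ActuatorConfig, mix: MixtureComposition,
                   params: OsmoticModelParams):
    """Return (names, y0, rhs).  State: [V, N_1..N_m] with N in mol, V in m^3."""
    species = chamber_species(mix)
    names = list(species)
    for sp in names:
        if sp not in config.membrane.sigma:
            raise KeyError(f"no reflection coefficient for species {sp!r}")
    sigma = np.array([config.membrane.sigma[sp] for sp in names])
    p_s = np.array([config.membrane.P_s.get(sp, 0.0) for sp in names])
    rt = params.R * params.T
    S = config.membrane.S_OM
    Sa = S * config.membrane.alpha_OM
    V0 = config.V_0
    turgor = config.mode == "turgor"
    k_over_V0 = config.k_BD / V0
    coupling = config.coupling

    # mol: molarity [mol/L] * V0 [m^3] * 1000 [L/m^3]
    y0 = np.empty(len(names) + 1)
    y0[0] = V0
    y0[1:] = np.array([species[sp] * V0 * 1000.0 for sp in names])

    if coupling is None:

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            V = y[0]
            c = y[1:] / V  # mol/m^3
            drive = rt * float(sigma @ c)
            P = k_over_V0 * (V - V0) if turgor else 0.0
            dV = Sa * (drive - P)
            dN = -p_s * S * c - (1.0 - sigma) * c * dV
            out = np.empty_like(y)
            out[0] = dV
            out[1:] = dN
            return out

    else:
        idx = {sp: i for i, sp in enumerate(names)}
        member_idx = [idx.get(m) for m in coupling.member_species]

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            V = y[0]
            c_tot = y[1:] / V  # mol/m^3
            totals = {
                m: (c_tot[i] / 1000.0 if i is not None else 0.0)
                for m, i in zip(coupling.member_species, member_idx)
            }
            spec = speciate(totals, coupling)
            c_free = c_tot.copy()
            for m, i in zip(coupling.member_species, member_idx):
                if i is not None:
                    c_free[i] = spec.free_concentration[m] * 1000.0
            c_complex = spec.complex_concentration * 1000.0
            # complexes: sigma = 1, P_s = 0 -- they drive but never leak
            drive = rt * (float(sigma @ c_free) + c_complex)
            P = k_over_V0 * (V - V0) if turgor else 0.0
            dV = Sa * (drive - P)
            dN = -p_s * S * c_free - (1.0 - sigma) * c_free * dV
            out = np.empty_like(y)
            out[0] = dV
            out[1:] = dN
            return out

    return names, y0, rhs


def _trace_from_solution(config: ActuatorConfig, names, t: np.ndarray,
                         y: np.ndarray, rt: float) -> TurgorTrace:
    V = y[0]
    amounts = {sp: y[1 + i] for i, sp in enumerate(names)}
    if config.mode == "turgor":
        pressure = config.k_BD * (V - config.V_0) / config.V_0
    else:
        pressure = np.zeros_like(V)
    n_total = y[1:].sum(axis=0)
    pi_internal = rt * n_total / V
    return TurgorTrace(
        time=t, volume=V, pressure=pressure,
        chamber_amounts=amounts, pi_internal=pi_internal,
    )


def simulate(
    config: ActuatorConfig,
    mix: MixtureComposition,
    duration: float,
    params: Optional[OsmoticModelParams] = None,
    n_samples: int = 201,
    rtol: float = 1e-8,
) -> TurgorTrace:
    """Integrate the actuator ODE with an adaptive RK45 scheme."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = params or OsmoticModelParams()
    names, y0, rhs = _build_problem(config, mix, params)
    t_eval = np.linspace(0.0, duration, n_samples)
    atol = np.full_like(y0, 1e-18)
    atol[0] = config.V_0 * 1e-12
    sol = solve_ivp(
        rhs, (0.0, duration), y0, method="RK45",
        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise RuntimeError("non-finite state in integration output")
    return _trace_from_solution(config, names, sol.t, sol.y, params.R * params.T)


def simulate_fixed_step(
    config: ActuatorConfig,
    mix: MixtureComposition,
    duration: float,
    dt: float,
    params: Optional[OsmoticModelParams] = None,
    sample_every: int = 1000,
) -> TurgorTrace:
    """Classical fixed-step RK4 integrator (independent oracle for `simulate`)."""
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    params = params or OsmoticModelParams()
    names, y0, rhs = _build_problem(config, mix, params)
    n_steps = int(round(duration / dt))
    y = y0.copy()
    ts = [0.0]
    ys = [y.copy()]
    t = 0.0
    half = 0.5 * dt
    sixth = dt / 6.0
    for step in range(1, n_steps + 1):
        k1 = rhs(t, y)
        k2 = rhs(t + half, y + half * k1)
        k3 = rhs(t + half, y + half * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = step * dt
        if step % sample_every == 0 or step == n_steps:
            ts.append(t)
            ys.append(y.copy())
    arr = np.array(ys).T
    return _trace_from_solution(
        config, names, np.array(ts), arr, params.R * params.T
    )


def equilibrium_pressure(
    config: ActuatorConfig,
    mix: MixtureComposition,
    params: Optional[OsmoticModelParams] = None,
) -> float:
    """Algebraic turgor plateau for a fully rejected solution (sigma=1, P_s=0).

    Solves ``k_BD (V - V_0)/V_0 = R*T*N_tot/V`` for V by scalar root finding.
    """
    if config.mode != "turgor":
        raise ValueError("equilibrium pressure is defined for turgor mode")
    params = params or OsmoticModelParams()
    rt = params.R * params.T
    n_tot = sum(chamber_species(mix).values()) * config.V_0 * 1000.0
    V0, k = config.V_0, config.k_BD

    def g(V: float) -> float:
        return k * (V - V0) / V0 - rt * n_tot / V

    hi = V0 * 2.0
    while g(hi) < 0:
        hi *= 2.0
    V_eq = brentq(g, V0, hi, xtol=V0 * 1e-15, rtol=1e-14)
    return k * (V_eq - V0) / V0


def _sigma_eff(config: ActuatorConfig, mix: Optional[MixtureComposition]) -> float:
    if mix is None:
        return 1.0
    species = chamber_species(mix)
    total = sum(species.values())
    if total == 0:
        return 1.0
    return sum(config.membrane.sigma[sp] * m for sp, m in species.items()) / total


def characteristic_time(
    config: ActuatorConfig,
    Pi_0: float,
    mix: Optional[MixtureComposition] = None,
) -> float:
    """Analytic characteristic actuation time, s.

    ``t_s = P_ref * V_0 / (S_OM * alpha_OM * k_BD * Pi_0 * sigma_eff)`` where
    ``sigma_eff`` is the amount-weighted mean reflection coefficient of the
    chamber contents (1 when no mixture is given).
    """
    if config.mode != "turgor":
        raise ValueError("characteristic time is defined for turgor mode")
    if Pi_0 <= 0:
        raise ValueError("Pi_0 must be positive")
    s_eff = _sigma_eff(config, mix)
    return config.P_ref * config.V_0 / (
        config.membrane.S_OM * config.membrane.alpha_OM
        * config.k_BD * Pi_0 * s_eff
    )


def characteristic_time_numeric(
    config: ActuatorConfig,
    mix: MixtureComposition,
    params: Optional[OsmoticModelParams] = None,
    max_time: float = 1e6,
    rtol: float = 1e-8,
) -> float:
    """Simulated time at which the turgor pressure first crosses P_ref."""
    if config.mode != "turgor":
        raise ValueError("characteristic time is defined for turgor mode")
    params = params or OsmoticModelParams()
    names, y0, rhs = _build_problem(config, mix, params)
    k_over_V0 = config.k_BD / config.V_0

    def crossed(t, y):
        return k_over_V0 * (y[0] - config.V_0) - config.P_ref

    crossed.terminal = True
    crossed.direction = 1.0
    atol = np.full_like(y0, 1e-18)
    atol[0] = config.V_0 * 1e-12
    sol = solve_ivp(rhs, (0.0, max_time), y0, method="RK45",
                    rtol=rtol, atol=atol, events=crossed)
    if not sol.t_events[0].size:
        raise RuntimeError("pressure never crossed P_ref within max_time")
    return float(sol.t_events[0][0])


def nondimensionalize(trace: TurgorTrace, t_s: float) -> TurgorTrace:
    """Return a copy of the trace with the time axis divided by ``t_s``."""
    if t_s <= 0:
        raise ValueError("t_s must be positive")
    return TurgorTrace(
        time=trace.time / t_s,
        volume=trace.volume.copy(),
        pressure=trace.pressure.copy(),
        chamber_amounts={k: v.copy() for k, v in trace.chamber_amounts.items()},
        pi_internal=trace.pi_internal.copy(),
        t_over_ts=trace.time / t_s,
    )
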