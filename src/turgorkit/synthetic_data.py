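"""Synthetic instrument data and parameter-recovery harnesses.

Generators mimic the statistical structure of the real measurements:

* cryo-osmometer replicates — i.i.d. Gaussian around the true potential with
  the per-mixture replicate standard deviation (n = 5),
* pressure traces — simulated turgor with additive Gaussian sensor noise,
  quantized at the sensor resolution (0.01 MPa) and clipped at full scale
  (1.72 MPa), in triplicate,
* piston-displacement traces — chamber volume gain divided by the piston
  cross-section plus Gaussian noise.

All generators are deterministic under a fixed root seed; replicate k uses
seed ``seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .actuator_sim import ActuatorConfig, TurgorTrace, simulate
from .association import (
    ComplexModel,
    effective_osmotic_potential,
    member_totals,
    speciate,
)
from .mixtures import MixtureComposition, OsmoticModelParams

__all__ = [
    "NoiseSpec",
    "DEFAULT_OSMOMETRY_SPEC",
    "DEFAULT_TRACE_SPEC",
    "SyntheticTraceSet",
    "quantize",
    "gen_osmometry",
    "gen_turgor_trace",
    "gen_piston_trace",
    "recover_permeability",
    "recover_association",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument noise model shared by all generators."""

    osmometry_sd: float = 0.02       # MPa, per-mixture replicate spread
    pressure_quantum: float = 0.01   # MPa, sensor resolution
    pressure_full_scale: float = 1.72  # MPa, sensor ceiling
    pressure_noise_sd: float = 0.005  # MPa
    displacement_noise_sd: float = 1e-5  # m
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.osmometry_sd, self.pressure_noise_sd,
               self.displacement_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.pressure_quantum <= 0:
            raise ValueError("pressure_quantum must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


DEFAULT_OSMOMETRY_SPEC = NoiseSpec(n_replicates=5)
DEFAULT_TRACE_SPEC = NoiseSpec(n_replicates=3)


@dataclass
class SyntheticTraceSet:
    """Noise-free base trace plus per-replicate noisy observations."""

    time: np.ndarray
    base: TurgorTrace
    replicates: list[np.ndarray]   # pressure in MPa, or displacement in m
    kind: str                      # "pressure" | "displacement"
    spec: NoiseSpec


def quantize(values: np.ndarray, quantum: float) -> np.ndarray:
    """Round to the nearest multiple of ``quantum`` (idempotent)."""
    return np.round(np.asarray(values, dtype=float) / quantum) * quantum


def gen_osmometry(true_pi: float, spec: NoiseSpec = DEFAULT_OSMOMETRY_SPEC) -> np.ndarray:
    """Replicate cryo-osmometry readings (MPa) around ``true_pi``."""
    if true_pi < 0:
        raise ValueError("true_pi must be >= 0")
    rng = np.random.default_rng(spec.seed)
    return true_pi + spec.osmometry_sd * rng.standard_normal(spec.n_replicates)


def gen_turgor_trace(
    config: ActuatorConfig,
    mix: MixtureComposition,
    spec: NoiseSpec = DEFAULT_TRACE_SPEC,
    duration: float = 240.0,
    params: Optional[OsmoticModelParams] = None,
    n_samples: int = 61,
) -> SyntheticTraceSet:
    """Quantized, clipped, noisy turgor-pressure traces (MPa)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    base = simulate(config, mix, duration, params, n_samples=n_samples)
    p_mpa = base.pressure / 1e6
    reps = []
    for k in range(spec.n_replicates):
        rng = np.random.default_rng(spec.seed + k)
        noisy = p_mpa + spec.pressure_noise_sd * rng.standard_normal(p_mpa.shape)
        noisy = np.clip(quantize(noisy, spec.pressure_quantum),
                        0.0, spec.pressure_full_scale)
        reps.append(noisy)
    return SyntheticTraceSet(time=base.time, base=base, replicates=reps,
                             kind="pressure", spec=spec)


def gen_piston_trace(
    config: ActuatorConfig,
    mix: MixtureComposition,
    spec: NoiseSpec = DEFAULT_TRACE_SPEC,
    duration: float = 4 * 3600.0,
    params: Optional[OsmoticModelParams] = None,
    n_samples: int = 61,
) -> SyntheticTraceSet:
    """Noisy piston-displacement traces (m) over a four-hour default window."""
    if config.mode != "piston":
        raise ValueError("piston traces require a piston-mode config")
    if config.piston_area is None or config.piston_area <= 0:
        raise ValueError("config.piston_area must be set and positive")
    base = simulate(config, mix, duration, params, n_samples=n_samples)
    disp = (base.volume - config.V_0) / config.piston_area
    reps = []
    for k in range(spec.n_replicates):
        rng = np.random.default_rng(spec.seed + k)
        reps.append(disp + spec.displacement_noise_sd
                    * rng.standard_normal(disp.shape))
    return SyntheticTraceSet(time=base.time, base=base, replicates=reps,
                             kind="displacement", spec=spec)


def recover_permeability(
    traces: SyntheticTraceSet,
    config: ActuatorConfig,
    mix: MixtureComposition,
    params: Optional[OsmoticModelParams] = None,
    log10_halfwidth: float = 2.0,
) -> tuple[float, float]:
    """Least-squares fit of the membrane water permeability to trace(s).

    Re-simulates at trial ``alpha_OM`` values and minimizes squared residuals
    of pressure (MPa) or displacement (m) independently per replicate; returns
    the across-replicate mean estimate and standard deviation.  The search is
    over log10(alpha) in a window around the configured value, which acts as
    the (possibly wrong) initial guess.
    """
    if not traces.replicates:
        raise ValueError("need at least one trace")
    t = traces.time
    duration = float(t[-1])
    n_samples = len(t)
    center = np.log10(config.membrane.alpha_OM)

    def predict(log10_alpha: float) -> np.ndarray:
        membrane = replace(config.membrane, alpha_OM=10.0 ** log10_alpha)
        cfg = replace(config, membrane=membrane)
        trace = simulate(cfg, mix, duration, params, n_samples=n_samples)
        if traces.kind == "pressure":
            return trace.pressure / 1e6
        return (trace.volume - config.V_0) / config.piston_area

    estimates = []
    for obs in traces.replicates:
        if float(np.ptp(obs)) == 0.0:
            raise ValueError("degenerate (flat) trace")

        def sse(log10_alpha: float, _obs=obs) -> float:
            r = predict(log10_alpha) - _obs
            return float(r @ r)

        res = minimize_scalar(
            sse, bounds=(center - log10_halfwidth, center + log10_halfwidth),
            method="bounded", options={"xatol": 1e-5},
        )
        estimates.append(10.0 ** res.x)
    est = np.array(estimates)
    return float(est.mean()), float(est.std(ddof=1)) if len(est) > 1 else 0.0


def recover_association(
    dilution_factors: Sequence[float],
    measured_pi: Sequence[float],
    mix: MixtureComposition,
    params: Optional[OsmoticModelParams] = None,
    log10_bounds: tuple[float, float] = (-6.0, 6.0),
) -> tuple[float, float]:
    """Fit the association constant to a dilution-series osmometry table.

    Returns ``(degree_percent_at_stock, K_assoc)`` minimizing the squared
    mismatch between the effective osmotic potential and the measurements.
    """
    factors = np.asarray(list(dilution_factors), dtype=float)
    pi_obs = np.asarray(list(measured_pi), dtype=float)
    if factors.size < 2:
        raise ValueError("need measurements at >= 2 dilution factors")
    if factors.size != pi_obs.size:
        raise ValueError("factors and measurements differ in length")
    totals0 = member_totals(mix)

    def predict(K: float) -> np.ndarray:
        model = ComplexModel(K_assoc=K)
        out = np.empty_like(factors)
        for j, lam in enumerate(factors):
            spec = speciate({m: v / lam for m, v in totals0.items()}, model)
            out[j] = effective_osmotic_potential(spec, params)
        return out

    def sse(log10_K: float) -> float:
        r = predict(10.0 ** log10_K) - pi_obs
        return float(r @ r)

    # compare the best finite-K fit against K = 0 (no association)
    res = minimize_scalar(sse, bounds=log10_bounds, method="bounded",
                          options={"xatol": 1e-7})
    r0 = predict(0.0) - pi_obs
    if float(r0 @ r0) <= res.fun:
        k_hat = 0.0
    else:
        k_hat = 10.0 ** res.x
    spec = speciate(totals0, ComplexModel(K_assoc=k_hat))
    return 100.0 * spec.fraction_associated, k_hat
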