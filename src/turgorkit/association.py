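"""Mass-action model of the four-member K+/Cl-/D-Glc/L-Gln complex.

A single 1:1:1:1 complex with association constant ``K_assoc`` ((L/mol)^3) is
assumed; activity equals concentration.  The association extent ``x`` solves

    x = K_assoc * prod_m (total_m - x),       x in [0, min_m total_m]

which has a unique root on that interval because the right-hand side is
strictly decreasing while the left-hand side increases.  The fraction of
osmolytes bound is ``4 x / sum_m total_m``.  Diluting a mixture shifts the
equilibrium toward dissociation, so the complexed pool buffers the effective
osmotic potential against dilution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import math

import numpy as np
import pandas as pd

from .mixtures import (
    DEFAULT_SPECIES,
    MixtureComposition,
    OsmoticModelParams,
    gamma_factor,
    rt_mpa_per_molar,
)

__all__ = [
    "COMPLEX_MEMBERS",
    "ComplexModel",
    "Speciation",
    "UnreachableTargetError",
    "member_totals",
    "speciate",
    "calibrate_K",
    "effective_osmotic_potential",
    "dilution_curve",
    "default_gammas",
]

#: Ordered members of the complex.
COMPLEX_MEMBERS: tuple[str, ...] = ("K+", "Cl-", "D-Glc", "L-Gln")

_BISECT_REL_TOL = 1e-12


class UnreachableTargetError(ValueError):
    """Raised when a target association degree exceeds the stoichiometric ceiling."""


@dataclass(frozen=True)
class ComplexModel:
    """1:1:1:1 four-member complex with one association constant."""

    K_assoc: float
    member_species: tuple[str, ...] = COMPLEX_MEMBERS
    n_members: int = 4

    def __post_init__(self) -> None:
        if not math.isfinite(self.K_assoc) or self.K_assoc < 0:
            raise ValueError("K_assoc must be finite and >= 0")
        if self.n_members != len(self.member_species) or self.n_members != 4:
            raise ValueError("the complex model is defined for exactly 4 members")


@dataclass(frozen=True)
class Speciation:
    """Equilibrium free/bound concentrations (mol/L) for one total vector."""

    free_concentration: Mapping[str, float]
    complex_concentration: float
    effective_particle_molarity: float
    fraction_associated: float
    totals: Mapping[str, float]


def default_gammas(params: Optional[OsmoticModelParams] = None) -> dict[str, float]:
    """Per-member non-ideality weights consistent with the mixture estimator.

    K+ and Cl- each carry the salt's osmotic coefficient phi so that at zero
    association the ion pair reproduces gamma_KCl = phi * i exactly.
    """
    params = params or OsmoticModelParams()
    phi = DEFAULT_SPECIES["KCl"].phi
    return {
        "K+": phi,
        "Cl-": phi,
        "D-Glc": gamma_factor(DEFAULT_SPECIES["D-Glc"], params),
        "L-Gln": gamma_factor(DEFAULT_SPECIES["L-Gln"], params),
    }


def member_totals(mix: MixtureComposition) -> dict[str, float]:
    """Total member concentrations (mol/L); KCl supplies K+ and Cl- each."""
    totals = {m: 0.0 for m in COMPLEX_MEMBERS}
    for sp, molarity in mix.species_molarity.items():
        if sp == "KCl":
            totals["K+"] += molarity
            totals["Cl-"] += molarity
        elif sp in totals:
            totals[sp] += molarity
        else:
            raise KeyError(f"species {sp!r} is not a complex member")
    return totals


def _mass_action_rhs(x: float, totals_vec: Sequence[float], K: float) -> float:
    prod = 1.0
    for t in totals_vec:
        prod *= t - x
    return K * prod


def speciate(
    totals: Mapping[str, float],
    model: ComplexModel,
    gammas: Optional[Mapping[str, float]] = None,
) -> Speciation:
    """Solve the mass-action equilibrium for one total-concentration vector."""
    tot = {m: float(totals.get(m, 0.0)) for m in model.member_species}
    for m, t in tot.items():
        if t < 0:
            raise ValueError(f"negative total for {m}")
    vec = [tot[m] for m in model.member_species]
    x_max = min(vec)
    K = model.K_assoc

    if K == 0.0 or x_max == 0.0:
        x = 0.0
    else:
        # f(x) = x - K*prod(t - x) is increasing on [0, x_max]; bisect.
        lo, hi = 0.0, x_max
        while hi - lo > _BISECT_REL_TOL * x_max:
            mid = 0.5 * (lo + hi)
            if mid - _mass_action_rhs(mid, vec, K) > 0.0:
                hi = mid
            else:
                lo = mid
        x = 0.5 * (lo + hi)

    free = {m: tot[m] - x for m in model.member_species}
    total_members = sum(vec)
    fraction = (model.n_members * x / total_members) if total_members > 0 else 0.0
    g = gammas or default_gammas()
    eff = sum(g.get(m, 1.0) * c for m, c in free.items()) + x
    return Speciation(
        free_concentration=free,
        complex_concentration=x,
        effective_particle_molarity=eff,
        fraction_associated=fraction,
        totals=tot,
    )


def calibrate_K(
    mix: MixtureComposition,
    target_degree: float,
    model_template: Optional[ComplexModel] = None,
    log10_bracket: tuple[float, float] = (-9.0, 14.0),
    tol: float = 1e-9,
) -> ComplexModel:
    """Association constant reproducing a target association degree (%).

    Monotone bisection on log10(K) over ``log10_bracket``; raises
    :class:`UnreachableTargetError` when the target exceeds the
    limiting-reagent ceiling ``4 * min(totals) / sum(totals)``.
    """
    if not 0.0 <= target_degree < 100.0:
        raise ValueError("target_degree must be in [0, 100)")
    members = (model_template or ComplexModel(K_assoc=0.0)).member_species
    totals = member_totals(mix)
    if any(totals[m] <= 0 for m in members):
        raise ValueError("mixture must contain all four complex members")
    target = target_degree / 100.0
    if target == 0.0:
        return ComplexModel(K_assoc=0.0, member_species=members)

    vec = [totals[m] for m in members]
    ceiling = 4.0 * min(vec) / sum(vec)
    if target >= ceiling:
        raise UnreachableTargetError(
            f"target degree {target_degree}% is at or above the stoichiometric "
            f"ceiling {100.0 * ceiling:.4f}% for this composition"
        )

    def frac(log10_K: float) -> float:
        m = ComplexModel(K_assoc=10.0**log10_K, member_species=members)
        return speciate(totals, m).fraction_associated

    lo, hi = log10_bracket
    if frac(lo) > target or frac(hi) < target:
        raise UnreachableTargetError(
            "target degree not bracketed by the configured log10(K) range"
        )
    while hi - lo > 1e-13:
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) < tol:
            lo = hi = mid
            break
        if f < target:
            lo = mid
        else:
            hi = mid
    return ComplexModel(K_assoc=10.0 ** (0.5 * (lo + hi)), member_species=members)


def effective_osmotic_potential(
    spec: Speciation,
    params: Optional[OsmoticModelParams] = None,
    gammas: Optional[Mapping[str, float]] = None,
) -> float:
    """Effective osmotic potential (MPa) of a speciated mixture.

    Free members are weighted by the per-species non-ideality factors; each
    complex counts as a single ideal particle.  With K_assoc = 0 this equals
    the plain mixture estimate exactly.
    """
    params = params or OsmoticModelParams()
    g = gammas or default_gammas(params)
    rt = rt_mpa_per_molar(params)
    particles = (
        sum(g.get(m, 1.0) * c for m, c in spec.free_concentration.items())
        + spec.complex_concentration
    )
    return rt * particles


def dilution_curve(
    mix: MixtureComposition,
    model: ComplexModel,
    dilution_factors: Sequence[float],
    params: Optional[OsmoticModelParams] = None,
    gammas: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Speciation and effective potential at each dilution factor (>= 1)."""
    factors = np.asarray(list(dilution_factors), dtype=float)
    if factors.size == 0:
        raise ValueError("need at least one dilution factor")
    if np.any(factors < 1.0):
        raise ValueError("dilution factors must be >= 1")
    totals0 = member_totals(mix)
    rows = []
    for lam in factors:
        totals = {m: t / lam for m, t in totals0.items()}
        spec = speciate(totals, model, gammas)
        rows.append(
            {
                "factor": lam,
                "complex_M": spec.complex_concentration,
                "fraction_assoc": spec.fraction_associated,
                "pi_eff_MPa": effective_osmotic_potential(spec, params, gammas),
            }
        )
    return pd.DataFrame(rows)
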