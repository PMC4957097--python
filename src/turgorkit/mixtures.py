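"""Osmolyte mixtures and the non-ideal Van 't Hoff osmotic-potential estimator.

The osmotic potential of a mixture is estimated as the sum of per-species
contributions ``gamma_k * M_k * R * T`` where ``gamma_k`` folds all deviations
from ideal behaviour into a single concentration-independent factor:

* ideal solutes (D-glucose): gamma = 1,
* strong electrolytes (KCl): gamma = phi * i with osmotic coefficient phi and
  dissociation count i,
* L-glutamine: a pluggable non-ideality factor, by default a calibrated
  constant (~1.96 at neutral pH, between the naive zwitterion limits).

Derived statistics: the measured/estimated potential ratio and the osmolyte
association degree (fraction of osmolytes proposed to be bound in four-member
K+/Cl-/D-Glc/L-Gln complexes, reconstructed from the osmotic deficit).

Units: molarities are mol/L at the interface (converted to mol/m3 internally),
potentials are returned in MPa.  Display rounding is half-up, 2 d.p. for MPa
and ratios, 1 d.p. for degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "R_GAS",
    "DEFAULT_TEMPERATURE_K",
    "OsmolyteSpecies",
    "MixtureComposition",
    "OsmoticModelParams",
    "AssociationEstimate",
    "DEFAULT_SPECIES",
    "SPECIES_ORDER",
    "round_half_up",
    "rt_mpa_per_molar",
    "mixture_from_ratio",
    "gamma_factor",
    "estimate_osmotic_potential",
    "osmotic_potential_ratio",
    "association_degree",
    "anomer_fractions",
    "table1_report",
]

#: Universal gas constant, J K^-1 mol^-1.
R_GAS = 8.314

#: Default absolute temperature for the estimator, K (back-derived so the
#: single-salt reference and the salt+sugar two-component row reproduce their
#: tabulated potentials at two decimals).
DEFAULT_TEMPERATURE_K = 300.15

_REL_TOL = 1e-9


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals with ties going away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OsmolyteSpecies:
    """A dissolved osmolyte and its non-ideality policy."""

    name: str
    vant_hoff_i: int = 1
    phi: float = 1.0
    gamma_mode: str = "ideal"
    rejection_sigma: float = 1.0
    stokes_radius_nm: Optional[float] = None
    custom_gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.vant_hoff_i < 1:
            raise ValueError(f"{self.name}: vant_hoff_i must be >= 1")
        if not 0.0 < self.phi <= 1.2:
            raise ValueError(f"{self.name}: phi must be in (0, 1.2]")
        if not 0.0 <= self.rejection_sigma <= 1.0:
            raise ValueError(f"{self.name}: rejection_sigma must be in [0, 1]")
        if self.gamma_mode not in ("ideal", "electrolyte", "amino_acid", "custom-constant"):
            raise ValueError(f"{self.name}: unknown gamma_mode {self.gamma_mode!r}")
        if self.gamma_mode == "custom-constant" and self.custom_gamma is None:
            raise ValueError(f"{self.name}: custom-constant mode requires custom_gamma")


#: Canonical species order used when parsing ratio strings.
SPECIES_ORDER: tuple[str, ...] = ("KCl", "D-Glc", "L-Gln")

DEFAULT_SPECIES: dict[str, OsmolyteSpecies] = {
    "KCl": OsmolyteSpecies(
        name="KCl", vant_hoff_i=2, phi=0.90, gamma_mode="electrolyte",
        rejection_sigma=0.6, stokes_radius_nm=0.13,
    ),
    "D-Glc": OsmolyteSpecies(name="D-Glc", gamma_mode="ideal", rejection_sigma=0.99),
    "L-Gln": OsmolyteSpecies(name="L-Gln", gamma_mode="amino_acid", rejection_sigma=1.0),
}


@dataclass(frozen=True)
class OsmoticModelParams:
    """Parameters of the modified Van 't Hoff estimator.

    ``gamma_gln_hook`` may supply a closed-form amino-acid non-ideality factor
    (e.g. a pK1/pK2/pH ionisation model); when absent the calibrated constant
    ``gamma_gln_constant`` is used.
    """

    R: float = R_GAS
    T: float = DEFAULT_TEMPERATURE_K
    pK1: float = 2.17
    pK2: float = 9.13
    pH: float = 7.0
    gamma_gln_constant: float = 1.96
    gamma_gln_hook: Optional[Callable[["OsmoticModelParams"], float]] = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if not self.pK1 < self.pK2:
            raise ValueError("pK1 must be below pK2")


def rt_mpa_per_molar(params: OsmoticModelParams) -> float:
    """R*T expressed in MPa per (mol/L): the potential of a 1 M ideal solute."""
    return params.R * params.T * 1000.0 / 1e6


@dataclass(frozen=True)
class MixtureComposition:
    """Named osmolyte mixture: molarities (mol/L), total molarity, pH."""

    species_molarity: Mapping[str, float]
    total_molarity: float
    pH: float = 7.0
    name: str = ""
    ratio_string: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_molarity", dict(self.species_molarity))
        for sp, m in self.species_molarity.items():
            if m < 0:
                raise ValueError(f"negative molarity for {sp}")
        if self.total_molarity < 0:
            raise ValueError("total_molarity must be >= 0")
        s = sum(self.species_molarity.values())
        scale = max(abs(self.total_molarity), 1.0)
        if abs(s - self.total_molarity) > _REL_TOL * scale:
            raise ValueError(
                f"molarities sum to {s}, not total_molarity={self.total_molarity}"
            )

    @property
    def n_components(self) -> int:
        return sum(1 for m in self.species_molarity.values() if m > 0)

    def scaled(self, factor: float) -> "MixtureComposition":
        """Mixture with every molarity multiplied by ``factor``."""
        return replace(
            self,
            species_molarity={k: v * factor for k, v in self.species_molarity.items()},
            total_molarity=self.total_molarity * factor,
        )

    def ratio_ints(self, max_denominator: int = 10**6) -> tuple[int, ...]:
        """Smallest integer ratio of molarities in canonical species order."""
        if self.total_molarity <= 0:
            raise ValueError("ratio undefined for an empty mixture")
        fracs = [
            Fraction(self.species_molarity.get(sp, 0.0) / self.total_molarity
                     ).limit_denominator(max_denominator)
            for sp in SPECIES_ORDER
        ]
        lcm = math.lcm(*(f.denominator for f in fracs))
        ints = [int(f * lcm) for f in fracs]
        g = math.gcd(*ints)
        return tuple(i // g for i in ints) if g else tuple(ints)


def mixture_from_ratio(
    ratio_string: str,
    total_molarity: float,
    pH: float = 7.0,
    name: str = "",
    species_order: Sequence[str] = SPECIES_ORDER,
) -> MixtureComposition:
    """Build a mixture from a ratio string like ``"5:12:3"``.

    The k-th species gets molarity ``total_molarity * ratio_k / sum(ratios)``;
    a zero ratio means the species is absent.
    """
    parts = [p.strip() for p in ratio_string.split(":")]
    if len(parts) != len(species_order) or any(p == "" for p in parts):
        raise ValueError(
            f"ratio string {ratio_string!r} needs {len(species_order)} entries"
        )
    try:
        ratios = [int(p) for p in parts]
    except ValueError as exc:
        raise ValueError(f"non-integer ratio in {ratio_string!r}") from exc
    if any(r < 0 for r in ratios):
        raise ValueError(f"negative ratio in {ratio_string!r}")
    total_ratio = sum(ratios)
    if total_ratio == 0:
        raise ValueError("all-zero ratio string")
    if total_molarity <= 0:
        raise ValueError("total_molarity must be positive")
    molarity = {
        sp: total_molarity * r / total_ratio
        for sp, r in zip(species_order, ratios)
        if r > 0
    }
    return MixtureComposition(
        species_molarity=molarity,
        total_molarity=total_molarity,
        pH=pH,
        name=name,
        ratio_string=ratio_string,
    )


def gamma_factor(species: OsmolyteSpecies, params: OsmoticModelParams) -> float:
    """Non-ideality factor of a species under the given parameter set."""
    mode = species.gamma_mode
    if mode == "ideal":
        return 1.0
    if mode == "electrolyte":
        return species.phi * species.vant_hoff_i
    if mode == "amino_acid":
        if params.gamma_gln_hook is not None:
            return float(params.gamma_gln_hook(params))
        return params.gamma_gln_constant
    if mode == "custom-constant":
        return float(species.custom_gamma)
    raise ValueError(f"unknown gamma_mode {mode!r}")


def estimate_osmotic_potential(
    mix: MixtureComposition,
    params: Optional[OsmoticModelParams] = None,
    registry: Optional[Mapping[str, OsmolyteSpecies]] = None,
) -> float:
    """Estimated osmotic potential of a mixture, in MPa.

    Sum over species of ``gamma_k * M_k * R * T`` with M in mol/m3.
    """
    params = params or OsmoticModelParams()
    registry = registry or DEFAULT_SPECIES
    rt = rt_mpa_per_molar(params)
    total = 0.0
    for sp_name, molarity in mix.species_molarity.items():
        if sp_name not in registry:
            raise KeyError(f"unknown species {sp_name!r}")
        total += gamma_factor(registry[sp_name], params) * molarity * rt
    return total


def osmotic_potential_ratio(measured: float, estimated: float) -> float:
    """Measured-over-estimated osmotic potential quotient."""
    if estimated <= 0:
        raise ValueError("estimated potential must be positive")
    if measured < 0:
        raise ValueError("measured potential must be >= 0")
    return measured / estimated


def association_degree(
    ratio: float, *, n_members: int = 4, deficit_multiplier: float = 1.5
) -> float:
    """Osmolyte association degree (%) from the osmotic potential ratio.

    The ratio is first rounded to two decimals (table display convention);
    the deficit ``1 - ratio`` is scaled by 3/2 — the multiplier consistent
    with all tabulated degrees for the four-member complex — and floored at 0.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    r2 = Decimal(repr(round_half_up(ratio, 2)))
    degree = Decimal(repr(deficit_multiplier)) * Decimal(100) * (Decimal(1) - r2)
    return max(0.0, float(degree))


def anomer_fractions(
    intensity_alpha: float, intensity_beta: float
) -> tuple[float, float]:
    """Percent alpha/beta anomer fractions from two peak intensities."""
    if intensity_alpha < 0 or intensity_beta < 0:
        raise ValueError("intensities must be >= 0")
    total = intensity_alpha + intensity_beta
    if total == 0:
        raise ValueError("both intensities are zero")
    return 100.0 * intensity_alpha / total, 100.0 * intensity_beta / total


@dataclass(frozen=True)
class AssociationEstimate:
    """Measured/estimated potential pair with its derived statistics."""

    measured_potential: float
    estimated_potential: float
    ratio: float
    association_degree_percent: float
    n_members: int = 4
    deficit_multiplier: float = 1.5

    @classmethod
    def from_measurement(
        cls, measured: float, estimated: float
    ) -> "AssociationEstimate":
        ratio = osmotic_potential_ratio(measured, estimated)
        return cls(
            measured_potential=measured,
            estimated_potential=estimated,
            ratio=ratio,
            association_degree_percent=association_degree(ratio),
        )


def table1_report(
    entries: Sequence[tuple],
    params: Optional[OsmoticModelParams] = None,
    registry: Optional[Mapping[str, OsmolyteSpecies]] = None,
) -> pd.DataFrame:
    """Assemble the derived-statistics table for a list of mixtures.

    ``entries`` holds ``(mixture, measured_MPa)`` or
    ``(mixture, measured_MPa, estimated_ref_MPa)`` tuples; when the third
    element is given it is used as the reference estimate for the ratio and
    degree columns (the estimated column always reports the model value).
    The degree is only reported for three-component mixtures.
    """
    if not entries:
        raise ValueError("entries must be nonempty")
    params = params or OsmoticModelParams()
    rows = []
    for entry in entries:
        mix, measured = entry[0], entry[1]
        estimated_ref = entry[2] if len(entry) > 2 and entry[2] is not None else None
        estimated = estimate_osmotic_potential(mix, params, registry)
        ref = estimated_ref if estimated_ref is not None else round_half_up(estimated, 2)
        if measured is not None:
            ratio = osmotic_potential_ratio(measured, ref)
            degree = (
                association_degree(ratio) if mix.n_components >= 3 else float("nan")
            )
            ratio_disp = round_half_up(ratio, 2)
        else:
            ratio_disp = float("nan")
            degree = float("nan")
        rows.append(
            {
                "name": mix.name,
                "total_M": mix.total_molarity,
                "measured_MPa": measured if measured is not None else float("nan"),
                "estimated_MPa": round_half_up(estimated, 2),
                "ratio": ratio_disp,
                "assoc_degree_pct": round_half_up(degree, 1)
                if not math.isnan(degree)
                else degree,
            }
        )
    return pd.DataFrame(rows)
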