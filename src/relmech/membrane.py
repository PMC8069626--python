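"""Porous-membrane hydraulics and osmosis auxiliaries.

For a film pierced by ``n`` cylindrical pores of radius ``a`` the laminar
(Poiseuille) pressure drop, the hydraulic permeability Lp, the reflection
coefficient σ computed from the solute-to-pore radius ratio ∅, and the
WLF-type free-volume-fraction coefficient f_g = B·Δα·A/2.303.

Pressures are Pa internally; the osmotic gradient Δπ is accepted in atm at
the API boundary (1 atm = 101325 Pa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "MembraneSpec",
    "ATM_PA",
    "pressure_drop",
    "hydraulic_permeability",
    "reflection_coefficient",
    "free_volume_fraction",
    "osmosis_dominance_check",
]

#: Pascals per standard atmosphere.
ATM_PA = 101325.0


@dataclass(frozen=True)
class MembraneSpec:
    """Porous-membrane description.

    ``pore_radius`` a (m), ``pore_density`` n (pores per membrane),
    ``thickness`` δ (m), ``viscosity`` η (Pa·s) and the solute-to-pore radius
    ratio ``solute_pore_ratio`` ∅ ∈ [0, 1] (measured, e.g., from microscopy).
    """

    pore_radius: float
    pore_density: float
    thickness: float
    viscosity: float
    solute_pore_ratio: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pore_radius", "pore_density", "thickness", "viscosity"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        if not 0.0 <= self.solute_pore_ratio <= 1.0:
            raise DomainError("solute_pore_ratio must lie in [0, 1]")


def pressure_drop(spec: MembraneSpec, Jv: float) -> float:
    """Poiseuille pressure drop ΔP = 8·η·δ·Jv / (n·π·a⁴) across the pores, Pa.

    ``Jv`` is the volumetric flux in m³·m⁻²·s⁻¹ (≥ 0); laminar incompressible
    flow is assumed.
    """
    if Jv < 0:
        raise DomainError("Jv must be nonnegative")
    return 8.0 * spec.viscosity * spec.thickness * Jv / (
        spec.pore_density * np.pi * spec.pore_radius**4
    )


def hydraulic_permeability(spec: MembraneSpec) -> float:
    """Hydraulic permeability Lp = n·π·a⁴ / (8·η·δ), the inverse slope of
    :func:`pressure_drop` so that Jv = ΔP·Lp exactly."""
    return spec.pore_density * np.pi * spec.pore_radius**4 / (
        8.0 * spec.viscosity * spec.thickness
    )


def reflection_coefficient(phi: float) -> float:
    """Reflection coefficient σ = (1 − (1−∅)²)² from the solute/pore radius ratio.

    σ = 0 for a fully open pore (∅ = 0) and 1 for a perfectly semipermeable
    membrane (∅ = 1); monotone increasing in between.
    """
    if not 0.0 <= phi <= 1.0:
        raise DomainError(f"phi must lie in [0, 1]; got {phi}")
    return (1.0 - (1.0 - phi) ** 2) ** 2


def free_volume_fraction(B: float, delta_alpha: float, A_wlf: float) -> float:
    """WLF-type free-volume-fraction coefficient f_g = B·Δα·A / 2.303.

    ``B`` is the proportionality constant (dimensionless), ``delta_alpha`` the
    thermal-expansion increment at the glass transition (K⁻¹) and ``A_wlf``
    the WLF coefficient (K).  All inputs must be positive.
    """
    for name, v in (("B", B), ("delta_alpha", delta_alpha), ("A_wlf", A_wlf)):
        if not v > 0:
            raise DomainError(f"{name} must be strictly positive; got {v}")
    return B * delta_alpha * A_wlf / 2.303


def osmosis_dominance_check(delta_pi_atm: float, delta_P_pa: float,
                            factor: float = 10.0) -> tuple[bool, float]:
    """Check the osmotic-pumping validity condition Δπ ≫ ΔP.

    Converts Δπ (atm) and ΔP (Pa) to a common unit and returns
    ``(dominates, ratio)`` where ``ratio = Δπ[Pa] / ΔP[Pa]`` (``inf`` when
    ΔP = 0 and Δπ > 0) and ``dominates`` is True when the ratio exceeds
    ``factor`` (default 10).
    """
    if delta_pi_atm < 0 or delta_P_pa < 0:
        raise DomainError("pressures must be nonnegative")
    pi_pa = delta_pi_atm * ATM_PA
    if delta_P_pa == 0.0:
        ratio = np.inf if pi_pa > 0 else 0.0
    else:
        ratio = pi_pa / delta_P_pa
    return bool(ratio > factor), float(ratio)
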