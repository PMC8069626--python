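"""Forward models for the three drug-release mechanisms and their composite.

A cumulative release profile Mt/M∞(t) from a thin non-degradable polymer film
is modelled as a convex combination of three mechanism curves:

* **burst release** — first-order liberation of drug at or near the film
  surface, ``F1(t) = 1 - exp(-k_b t)``;
* **Fickian diffusion** — transport through the polymer matrix under perfect
  sink conditions, the plane-sheet series solution of Fick's second law;
* **osmotic pumping** — zero-order release driven by the osmotic pressure
  gradient Δπ across the film acting as a semi-permeable membrane,
  ``F3(t) = k_os t`` with ``k_os = γ Δπ``.

The composite is ``Mt/M∞ = μ1 F1 + μ2 F2 + μ3 F3`` with the mechanism weights
μ on the probability simplex (Σμ = 1, μi ∈ [0, 1]); 100·μi is the percentage
contribution of mechanism i to the total release.

Units: time in hours, lengths in metres, D_e in m²/h, Δπ in atm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConstraintViolationError, DomainError, InputError

__all__ = [
    "ReleaseProfile",
    "CompositeParams",
    "GeometryConstants",
    "DEFAULT_THICKNESS",
    "DEFAULT_GAMMA",
    "burst_fraction",
    "diffusion_fraction",
    "diffusion_early_approx",
    "osmotic_fraction",
    "osmotic_slope",
    "delta_pi_from_slope",
    "composite_release",
]

#: Default film thickness h, metres (2 mm film).
DEFAULT_THICKNESS = 0.002

#: Default osmotic conversion factor γ = A·h·K′·S/M∞ in h⁻¹·atm⁻¹, so that
#: k_os = γ·Δπ.  Chosen so Δπ = 0.009 atm maps to a zero-order slope of
#: 0.01 h⁻¹ (release completing in ~100 h); configurable everywhere it is used.
DEFAULT_GAMMA = 1.111

#: Truncation tolerance and hard term cap for the plane-sheet series.
SERIES_TOL = 1e-12
SERIES_MAX_TERMS = 10_000

#: Tolerance on Σμ = 1.
WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ReleaseProfile:
    """A cumulative release curve: fraction released Mt/M∞ on a time grid.

    Parameters
    ----------
    times
        Sampling times in hours; strictly increasing, first value ≥ 0.
    fractions
        Cumulative fraction released at each time, dimensionless.
    label
        Free-text condition identifier (e.g. ``"PU-20%DE-Q7.5"``).
    """

    times: np.ndarray
    fractions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)
        if times.ndim != 1 or fractions.ndim != 1:
            raise InputError("times and fractions must be 1-D")
        if times.shape != fractions.shape:
            raise InputError(
                f"length mismatch: {times.size} times vs {fractions.size} fractions"
            )
        if times.size and times[0] < 0:
            raise InputError("times must start at or after 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
            raise InputError(f"times must be strictly increasing (violated at point {bad})")
        if not np.all(np.isfinite(fractions)):
            raise InputError("fractions must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CompositeParams:
    """Parameters of the three-mechanism composite release model.

    Attributes
    ----------
    mu
        Mechanism weights ``(μ_burst, μ_diffusion, μ_osmosis)`` on the simplex.
    k_b
        Burst rate constant, h⁻¹.
    D_e
        Effective diffusion coefficient, m²/h.
    k_os
        Osmotic zero-order slope, fraction·h⁻¹ (= γ·Δπ).
    """

    mu: np.ndarray
    k_b: float
    D_e: float
    k_os: float

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if mu.shape != (3,):
            raise ConstraintViolationError("mu must be a 3-vector (burst, diffusion, osmosis)")
        if np.any(mu < -WEIGHT_SUM_TOL) or np.any(mu > 1 + WEIGHT_SUM_TOL):
            raise ConstraintViolationError(f"each weight must lie in [0, 1]; got {mu}")
        if abs(mu.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ConstraintViolationError(
                f"mechanism weights must sum to 1 within {WEIGHT_SUM_TOL}; got sum {mu.sum()!r}"
            )
        if not self.k_b > 0:
            raise DomainError(f"k_b must be positive; got {self.k_b}")
        if not self.D_e > 0:
            raise DomainError(f"D_e must be positive; got {self.D_e}")
        if self.k_os < 0:
            raise DomainError(f"k_os must be nonnegative; got {self.k_os}")

    @property
    def mu_burst(self) -> float:
        return float(self.mu[0])

    @property
    def mu_diffusion(self) -> float:
        return float(self.mu[1])

    @property
    def mu_osmosis(self) -> float:
        return float(self.mu[2])

    def delta_pi(self, gamma: float = DEFAULT_GAMMA) -> float:
        """Osmotic pressure gradient in atm implied by k_os under ``gamma``."""
        return delta_pi_from_slope(gamma, self.k_os)


@dataclass(frozen=True)
class GeometryConstants:
    """Film geometry and osmotic physics bundle.

    ``area`` (A, m²), ``thickness`` (h, m), ``solubility`` (S, kg/m³),
    ``loaded_mass`` (M∞, kg) and ``permeability`` (K′, the lumped product of
    hydraulic permeability and reflection coefficient, in units such that
    A·h·K′·S/M∞ is h⁻¹·atm⁻¹).
    """

    area: float
    thickness: float = DEFAULT_THICKNESS
    solubility: float = 1.0
    loaded_mass: float = 1.0
    permeability: float = 1.0

    def __post_init__(self) -> None:
        for name in ("area", "thickness", "solubility", "loaded_mass", "permeability"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")

    @property
    def gamma(self) -> float:
        """Conversion factor γ = A·h·K′·S/M∞ (h⁻¹·atm⁻¹) with k_os = γ·Δπ."""
        return self.area * self.thickness * self.permeability * self.solubility / self.loaded_mass


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be nonnegative")
    return t


def burst_fraction(k_b: float, t):
    """First-order burst release ``1 - exp(-k_b t)``.

    Parameters
    ----------
    k_b
        Burst rate constant, h⁻¹ (> 0).
    t
        Time(s) in hours, scalar or array, ≥ 0.
    """
    if not k_b > 0:
        raise DomainError(f"k_b must be positive; got {k_b}")
    t = _check_time(t)
    return -np.expm1(-k_b * t)


def _series_terms_needed(tau_min: float, tol: float, max_terms: int) -> int:
    # smallest N with exp(-(2N+1)^2 pi^2 tau) / (2N+1)^2 < tol
    if tau_min <= 0:
        return max_terms
    n = 0.5 * (np.sqrt(np.log(max(1.0 / tol, 2.0)) / (np.pi**2 * tau_min)) - 1.0)
    return int(min(max_terms, max(4, np.ceil(n) + 2)))


def diffusion_fraction(D_e: float, thickness: float, t, tol: float = SERIES_TOL,
                       max_terms: int = SERIES_MAX_TERMS):
    """Plane-sheet Fickian release fraction under perfect sink conditions.

    Evaluates the odd-index series solution of Fick's second law for a film of
    thickness ``h``::

        Mt/M∞ = 1 - (8/π²) Σ_{n≥0} exp(-(2n+1)² π² D_e t / h²) / (2n+1)²

    truncated once the next term falls below ``tol`` (hard cap ``max_terms``).
    The odd-index form satisfies Mt/M∞(0) = 0 exactly (Σ 1/(2n+1)² = π²/8).

    Parameters
    ----------
    D_e
        Effective diffusion coefficient, m²/h (> 0).
    thickness
        Film thickness h in metres (> 0).
    t
        Time(s) in hours, ≥ 0.
    tol
        Truncation tolerance on the next omitted term (> 0).
    """
    if not D_e > 0:
        raise DomainError(f"D_e must be positive; got {D_e}")
    if not thickness > 0:
        raise DomainError(f"thickness must be positive; got {thickness}")
    if not tol > 0:
        raise DomainError("tol must be positive")
    t = _check_time(t)
    scalar = t.ndim == 0
    tau = np.atleast_1d(D_e * t / thickness**2)
    out = np.zeros_like(tau)
    pos = tau > 0
    if np.any(pos):
        tau_pos = tau[pos]
        n_terms = _series_terms_needed(float(tau_pos.min()), tol, max_terms)
        odd = 2 * np.arange(n_terms)[:, None] + 1  # (n_terms, 1)
        terms = np.exp(-(odd**2) * np.pi**2 * tau_pos[None, :]) / odd**2
        out[pos] = 1.0 - (8.0 / np.pi**2) * terms.sum(axis=0)
    return float(out[0]) if scalar else out


def diffusion_early_approx(D_e: float, thickness: float, t):
    """Early-time square-root law ``4 √(D_e t / (π h²))`` for plane-sheet release.

    Valid while the released fraction stays below ~60%; a warning is emitted
    when any returned value exceeds 0.6.
    """
    if not D_e > 0:
        raise DomainError(f"D_e must be positive; got {D_e}")
    if not thickness > 0:
        raise DomainError(f"thickness must be positive; got {thickness}")
    t = _check_time(t)
    result = 4.0 * np.sqrt(D_e * t / (np.pi * thickness**2))
    if np.any(np.asarray(result) > 0.6):
        warnings.warn(
            "early-time diffusion approximation evaluated beyond its ~60% validity range",
            stacklevel=2,
        )
    return result


def osmotic_fraction(k_os: float, t):
    """Zero-order osmotic release ``k_os · t``."""
    if k_os < 0:
        raise DomainError(f"k_os must be nonnegative; got {k_os}")
    t = _check_time(t)
    return k_os * t


def _gamma_of(geometry_or_gamma) -> float:
    if isinstance(geometry_or_gamma, GeometryConstants):
        return geometry_or_gamma.gamma
    gamma = float(geometry_or_gamma)
    if not gamma > 0:
        raise DomainError(f"gamma must be positive; got {gamma}")
    return gamma


def osmotic_slope(geometry_or_gamma, delta_pi: float) -> float:
    """Zero-order slope ``k_os = γ·Δπ`` with γ = A·h·K′·S/M∞.

    ``geometry_or_gamma`` may be a :class:`GeometryConstants` (γ computed from
    its fields) or the conversion factor γ itself in h⁻¹·atm⁻¹.
    """
    if delta_pi < 0:
        raise DomainError(f"delta_pi must be nonnegative; got {delta_pi}")
    return _gamma_of(geometry_or_gamma) * delta_pi


def delta_pi_from_slope(geometry_or_gamma, k_os: float) -> float:
    """Invert :func:`osmotic_slope`: Δπ = k_os / γ (atm)."""
    if k_os < 0:
        raise DomainError(f"k_os must be nonnegative; got {k_os}")
    return k_os / _gamma_of(geometry_or_gamma)


def composite_release(params: CompositeParams, times, thickness: float = DEFAULT_THICKNESS,
                      clamp: bool = False, series_tol: float = SERIES_TOL,
                      label: str = "") -> ReleaseProfile:
    """Simulate the weighted three-mechanism composite on a time grid.

    ``fraction(t) = μ1·F1(t) + μ2·F2(t) + μ3·F3(t)``.  The osmotic term is
    unbounded in t, so the composite is not clamped at 1 by default; pass
    ``clamp=True`` to cap simulated values at 1 beyond the fitted window.
    """
    times = _check_time(np.atleast_1d(times))
    f = (
        params.mu[0] * burst_fraction(params.k_b, times)
        + params.mu[1] * diffusion_fraction(params.D_e, thickness, times, tol=series_tol)
        + params.mu[2] * osmotic_fraction(params.k_os, times)
    )
    if clamp:
        f = np.minimum(f, 1.0)
    return ReleaseProfile(times=times, fractions=f, label=label)
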