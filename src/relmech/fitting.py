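"""Constrained least-squares fitting of the composite release model.

Given an observed cumulative-release profile, recover the parameter vector
X = (μ1, μ2, μ3, k_b, D_e, k_os) minimizing the unweighted sum of squared
residuals between the composite model and the observations, subject to the
simplex constraint Σμ = 1 (handled as an explicit equality by the SQP
engine), 0 ≤ μi ≤ 1, and positivity bounds on the kinetic constants.

Kinetic constants are optimized on a log10 internal scale (D_e spans many
decades), weights on the natural scale; results are reported on the natural
scale.  A deterministic multistart — simplex-lattice weight combinations
crossed with log-spaced kinetic constants — guards against local minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError
from .mechanisms import (
    DEFAULT_GAMMA,
    DEFAULT_THICKNESS,
    CompositeParams,
    GeometryConstants,
    ReleaseProfile,
    composite_release,
    delta_pi_from_slope,
)
from .sqp import OptimizationProblem, SQPSettings, solve_sqp

__all__ = ["FitSettings", "FitResult", "fit_release", "rmse", "r_squared", "multistart_grid"]

#: floor used when log-spacing a constant whose lower bound is 0
_LOG_FLOOR = 1e-4

#: minimum points required for a six-parameter fit
_MIN_POINTS = 6


@dataclass
class FitSettings:
    """Configuration of :func:`fit_release`.

    ``lattice_resolution`` controls the simplex-lattice of weight starts
    (resolution r gives C(r+2, 2) combinations; the centroid is appended when
    absent). ``n_kinetic`` log-spaced interior values per kinetic constant are
    crossed with the weight starts.  Bounds are wide enough to contain any
    plausible film-release kinetics. ``log_kinetics`` selects the internal
    log10 parameterization of k_b and D_e. ``seed`` is recorded for
    provenance; the default grid is fully deterministic.
    """

    lattice_resolution: int = 2
    include_centroid: bool = True
    n_kinetic: int = 2
    seed: int = 0
    k_b_bounds: tuple = (1e-3, 100.0)
    D_e_bounds: tuple = (1e-12, 1e-5)
    k_os_bounds: tuple = (0.0, 1.0)
    log_kinetics: bool = True
    series_tol: float = 1e-10
    thickness: float = DEFAULT_THICKNESS
    max_fraction: float = 1.2
    sqp: SQPSettings = field(default_factory=lambda: SQPSettings(tol=1e-9, max_iter=600))

    def __post_init__(self) -> None:
        if self.lattice_resolution < 1:
            raise InputError("lattice_resolution must be >= 1")
        if self.n_kinetic < 1:
            raise InputError("n_kinetic must be >= 1")
        for name in ("k_b_bounds", "D_e_bounds", "k_os_bounds"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi <= lo:
                raise InputError(f"{name} must be nonnegative and ordered")


@dataclass
class FitResult:
    """Outcome of a composite-model fit.

    ``contributions`` are the mechanism percentages (100·μ, summing to 100);
    ``delta_pi`` is the osmotic gradient in atm implied by the fitted slope
    under ``gamma`` (None when no conversion factor was supplied).
    """

    params: CompositeParams
    contributions: dict
    rmse: float
    r_squared: float
    converged: bool
    n_starts_used: int
    objective: float
    delta_pi: Optional[float] = None
    gamma: Optional[float] = None
    start_table: Optional[pd.DataFrame] = None

    @property
    def predicted(self) -> Optional[ReleaseProfile]:  # convenience, set by fit_release
        return getattr(self, "_predicted", None)


def rmse(observed, predicted) -> float:
    """Root-mean-squared error between paired observation and prediction vectors."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise InputError("observed and predicted must be equal-length nonempty vectors")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot about the observed mean."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size == 0:
        raise InputError("observed and predicted must be equal-length nonempty vectors")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateDataError("observed values have zero variance; R² is undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _simplex_lattice(resolution: int) -> list[np.ndarray]:
    pts = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            k = resolution - i - j
            pts.append(np.array([i, j, k], dtype=float) / resolution)
    return pts


def multistart_grid(settings: Optional[FitSettings] = None) -> list[np.ndarray]:
    """Deterministic multistart points in the natural parameter space.

    Returns 6-vectors (μ1, μ2, μ3, k_b, D_e, k_os): the simplex-lattice weight
    combinations (plus centroid) crossed with ``n_kinetic`` log-spaced interior
    values of each kinetic constant.  Every start satisfies Σμ = 1 and the
    bounds by construction; the list is identical across calls with equal
    settings.
    """
    if settings is None:
        settings = FitSettings()
    weights = _simplex_lattice(settings.lattice_resolution)
    if settings.include_centroid and not any(
        np.allclose(w, 1.0 / 3.0) for w in weights
    ):
        weights.append(np.full(3, 1.0 / 3.0))

    def interior_log(lo, hi, m):
        lo_eff = max(lo, _LOG_FLOOR * hi)
        q = np.linspace(0.0, 1.0, m + 2)[1:-1]
        return 10 ** (np.log10(lo_eff) + q * (np.log10(hi) - np.log10(lo_eff)))

    kb_vals = interior_log(*settings.k_b_bounds, settings.n_kinetic)
    de_vals = interior_log(*settings.D_e_bounds, settings.n_kinetic)
    kos_vals = interior_log(*settings.k_os_bounds, settings.n_kinetic)

    starts = []
    for w in weights:
        for kb, de, kos in zip(kb_vals, de_vals, kos_vals):
            starts.append(np.concatenate([w, [kb, de, kos]]))
    return starts


def _to_internal(x: np.ndarray, settings: FitSettings) -> np.ndarray:
    z = x.copy()
    if settings.log_kinetics:
        z[3] = math.log10(x[3])
        z[4] = math.log10(x[4])
    return z


def _from_internal(z: np.ndarray, settings: FitSettings) -> np.ndarray:
    x = z.copy()
    if settings.log_kinetics:
        x[3] = 10.0 ** z[3]
        x[4] = 10.0 ** z[4]
    return x


def _internal_bounds(settings: FitSettings) -> list[tuple]:
    kb_lo, kb_hi = settings.k_b_bounds
    de_lo, de_hi = settings.D_e_bounds
    kos_lo, kos_hi = settings.k_os_bounds
    if settings.log_kinetics:
        kb_b = (math.log10(kb_lo), math.log10(kb_hi))
        de_b = (math.log10(de_lo), math.log10(de_hi))
    else:
        kb_b = (kb_lo, kb_hi)
        de_b = (de_lo, de_hi)
    return [(0.0, 1.0)] * 3 + [kb_b, de_b, (kos_lo, kos_hi)]


def fit_release(profile: ReleaseProfile,
                geometry: Optional[GeometryConstants] = None,
                settings: Optional[FitSettings] = None,
                gamma: Optional[float] = None) -> FitResult:
    """Fit the composite three-mechanism model to an observed release profile.

    Minimizes Σ_t (model(t) − observed(t))² over the six parameters subject to
    the simplex and bound constraints, taking the best of the deterministic
    multistart.  The osmotic gradient Δπ is derived from the fitted slope via
    ``gamma`` (or ``geometry.gamma``; defaults to the documented conversion
    factor when neither is given).

    Raises
    ------
    InputError
        Fewer than 6 points, or fractions outside [0, 1.05].
    DegenerateDataError
        A constant (zero-variance) profile carries no kinetic information.
    """
    if settings is None:
        settings = FitSettings()
    times = profile.times
    obs = profile.fractions
    if times.size < _MIN_POINTS:
        raise InputError(
            f"too few points: need at least {_MIN_POINTS}, got {times.size}"
        )
    if np.any(obs < -1e-12) or np.any(obs > settings.max_fraction):
        # cumulative-release data may mildly exceed 1 (noise, normalization
        # slack, the unclamped zero-order osmotic term); far larger values
        # signal a scale error (e.g. percent or mass instead of fraction)
        raise InputError(
            f"observed fractions must lie in [0, {settings.max_fraction}]"
        )
    if np.ptp(obs) == 0.0:
        raise DegenerateDataError(
            "observed profile is constant; release kinetics are unidentifiable"
        )

    thickness = geometry.thickness if geometry is not None else settings.thickness
    if gamma is None:
        gamma = geometry.gamma if geometry is not None else DEFAULT_GAMMA

    ln10 = math.log(10.0)

    def _terms(z: np.ndarray):
        """Mechanism curves F and residual Jacobian on the internal scale."""
        x = _from_internal(z, settings)
        mu, k_b, D_e, k_os = x[:3], x[3], x[4], x[5]
        F1 = -np.expm1(-k_b * times)
        tau = D_e * times / thickness**2
        n_terms = _series_terms_needed_pos(tau, settings.series_tol)
        odd = 2 * np.arange(n_terms)[:, None] + 1
        E = np.exp(-(odd**2) * np.pi**2 * tau[None, :])
        F2 = 1.0 - (8.0 / np.pi**2) * (E / odd**2).sum(axis=0)
        F2 = np.where(times > 0, F2, 0.0)
        dF2_dtau = 8.0 * E.sum(axis=0) * (times > 0)
        F3 = k_os * times
        pred = mu[0] * F1 + mu[1] * F2 + mu[2] * F3
        J = np.empty((times.size, 6))
        J[:, 0], J[:, 1], J[:, 2] = F1, F2, F3
        J[:, 3] = mu[0] * times * np.exp(-k_b * times)
        J[:, 4] = mu[1] * dF2_dtau * times / thickness**2
        J[:, 5] = mu[2] * times
        if settings.log_kinetics:  # chain rule through x = 10**z
            J[:, 3] *= k_b * ln10
            J[:, 4] *= D_e * ln10
        return pred, J

    def sse(z: np.ndarray) -> float:
        pred, _ = _terms(z)
        return float(np.sum((pred - obs) ** 2))

    def sse_grad(z: np.ndarray) -> np.ndarray:
        pred, J = _terms(z)
        return 2.0 * (J.T @ (pred - obs))

    eq = [lambda z: z[0] + z[1] + z[2] - 1.0]
    eq_jac = [lambda z: np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])]
    bounds = _internal_bounds(settings)

    starts = multistart_grid(settings)
    records = []
    best = None
    for i, x0 in enumerate(starts):
        z0 = _to_internal(x0, settings)
        problem = OptimizationProblem(
            objective=sse, gradient=sse_grad, x0=z0,
            equality_constraints=eq, eq_jacobians=eq_jac, bounds=bounds,
        )
        sol = solve_sqp(problem, settings.sqp)
        records.append({
            "start": i, "objective": sol.fun, "converged": sol.converged,
            "iterations": sol.iterations, "kkt_residual": sol.kkt_residual,
        })
        key = (not sol.converged, sol.fun)
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    x_hat = _from_internal(sol.x, settings)
    mu_hat = np.clip(x_hat[:3], 0.0, 1.0)
    mu_hat = mu_hat / mu_hat.sum()  # exact simplex (solver leaves tol-level slack)
    k_b_hat = float(np.clip(x_hat[3], *settings.k_b_bounds))
    D_e_hat = float(np.clip(x_hat[4], *settings.D_e_bounds))
    k_os_hat = float(np.clip(x_hat[5], *settings.k_os_bounds))
    params = CompositeParams(mu=mu_hat, k_b=k_b_hat, D_e=D_e_hat, k_os=k_os_hat)
    predicted = composite_release(params, times, thickness=thickness,
                                  series_tol=settings.series_tol,
                                  label=profile.label)
    contributions = {
        "burst": 100.0 * params.mu_burst,
        "diffusion": 100.0 * params.mu_diffusion,
        "osmosis": 100.0 * params.mu_osmosis,
    }
    result = FitResult(
        params=params,
        contributions=contributions,
        rmse=rmse(obs, predicted.fractions),
        r_squared=r_squared(obs, predicted.fractions),
        converged=bool(sol.converged),
        n_starts_used=len(starts),
        objective=float(sol.fun),
        delta_pi=delta_pi_from_slope(gamma, params.k_os),
        gamma=float(gamma),
        start_table=pd.DataFrame.from_records(records),
    )
    object.__setattr__(result, "_predicted", predicted)
    return result


def _series_terms_needed_pos(tau: np.ndarray, tol: float, max_terms: int = 4000) -> int:
    pos = tau[tau > 0]
    if not pos.size:
        return 1
    tau_min = float(pos.min())
    n = 0.5 * (math.sqrt(math.log(max(1.0 / tol, 2.0)) / (math.pi**2 * tau_min)) - 1.0)
    return int(min(max_terms, max(4, math.ceil(n) + 2)))
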