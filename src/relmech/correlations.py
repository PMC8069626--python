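"""Factor correlations of the fitted kinetic constants and profile prediction.

Two empirical correlation families link a mechanism's kinetic constant to an
experimental factor:

* **inverse concentration** (Arrhenius-type): ``ln k = a + b·(1/C)`` with C
  the drug loading percentage;
* **linear flow**: ``k = a + b·Q`` with Q the flow rate in mL/s.

Both are fitted by ordinary least squares with an intercept; the
zero-intercept variants (``ln k = b/C``; ``k = b·Q``) are available behind
``zero_intercept=True``.  Fitted correlations predict the kinetic constants
of unseen conditions; mechanism weights are interpolated linearly in the
varied factor and renormalized to the simplex, and the predicted parameter
set is simulated forward to a full release profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InputError
from .mechanisms import (
    DEFAULT_GAMMA,
    DEFAULT_THICKNESS,
    CompositeParams,
    ReleaseProfile,
    composite_release,
    osmotic_slope,
)

__all__ = [
    "CorrelationModel",
    "fit_concentration_correlation",
    "fit_flow_correlation",
    "predict_constant",
    "predict_release_profile",
]


@dataclass(frozen=True)
class CorrelationModel:
    """A fitted one-factor correlation for one kinetic constant.

    ``kind`` is ``"inverse_concentration"`` (fit on the ln k vs 1/C scale) or
    ``"linear_flow"`` (k vs Q).  ``intercept``/``slope`` are the coefficients
    on the fitting scale; ``fit_r_squared`` the coefficient of determination
    on that scale; ``training_x`` the factor values used for the fit.
    """

    kind: str
    constant_name: str
    intercept: float
    slope: float
    fit_r_squared: float
    training_x: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("inverse_concentration", "linear_flow"):
            raise InputError(f"unknown correlation kind {self.kind!r}")
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise InputError("correlation coefficients must be finite")
        object.__setattr__(self, "training_x", np.asarray(self.training_x, dtype=float))
        if self.training_x.size < 2:
            raise InputError("a correlation needs at least 2 supporting points")


def _ls_line(x: np.ndarray, y: np.ndarray, zero_intercept: bool) -> tuple[float, float, float]:
    if zero_intercept:
        b = float(x @ y / (x @ x))
        a = 0.0
    else:
        b, a = np.polyfit(x, y, 1)
        a, b = float(a), float(b)
    resid = y - (a + b * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def fit_concentration_correlation(points: Sequence[tuple], constant_name: str = "k",
                                  zero_intercept: bool = False) -> CorrelationModel:
    """Fit ``ln k = a + b·(1/C)`` to (C, k) pairs by least squares.

    Requires at least two points with distinct positive concentrations and
    strictly positive constants.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InputError("need at least 2 (C, k) points")
    C, k = pts[:, 0], pts[:, 1]
    if np.unique(C).size < 2:
        raise InputError("concentrations must be distinct")
    if np.any(C <= 0):
        raise InputError("concentrations must be positive")
    if np.any(k <= 0):
        raise InputError("constants must be positive for a log-scale fit")
    a, b, r2 = _ls_line(1.0 / C, np.log(k), zero_intercept)
    return CorrelationModel("inverse_concentration", constant_name, a, b, r2, C)


def fit_flow_correlation(points: Sequence[tuple], constant_name: str = "k",
                         zero_intercept: bool = False) -> CorrelationModel:
    """Fit ``k = a + b·Q`` to (Q, k) pairs by least squares."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise InputError("need at least 2 (Q, k) points")
    Q, k = pts[:, 0], pts[:, 1]
    if np.unique(Q).size < 2:
        raise InputError("flow rates must be distinct")
    a, b, r2 = _ls_line(Q, k, zero_intercept)
    return CorrelationModel("linear_flow", constant_name, a, b, r2, Q)


def predict_constant(model: CorrelationModel, x: float,
                     extrapolation_band: float = 0.5) -> float:
    """Evaluate a fitted correlation at factor value ``x`` on the natural scale.

    Emits a warning (never an error) when ``x`` lies outside the training range
    widened by ``extrapolation_band`` times its span.
    """
    lo, hi = float(model.training_x.min()), float(model.training_x.max())
    band = extrapolation_band * max(hi - lo, 1e-300)
    if x < lo - band or x > hi + band:
        warnings.warn(
            f"{model.constant_name}: {x} is far outside the training range "
            f"[{lo}, {hi}]; extrapolated prediction",
            stacklevel=2,
        )
    if model.kind == "inverse_concentration":
        if x <= 0:
            raise InputError("concentration must be positive")
        return float(np.exp(model.intercept + model.slope / x))
    return float(model.intercept + model.slope * x)


def _interp_weights(weight_source: Sequence[tuple], x: float) -> np.ndarray:
    """Linear interpolation of (μ_burst, μ_diffusion, μ_osmosis) in the factor."""
    pts = sorted(weight_source, key=lambda p: p[0])
    xs = np.array([p[0] for p in pts], dtype=float)
    if np.unique(xs).size < 2:
        raise InputError("weights must be available at >= 2 distinct conditions")
    mus = np.array([np.asarray(p[1], dtype=float) for p in pts])
    mu = np.array([np.interp(x, xs, mus[:, i]) for i in range(3)])
    mu = np.clip(mu, 0.0, None)
    s = mu.sum()
    if s <= 0:
        raise InputError("interpolated weights degenerate to zero")
    return mu / s


def predict_release_profile(models: Mapping[str, CorrelationModel],
                            weight_source: Sequence[tuple],
                            x: float,
                            times,
                            gamma: float = DEFAULT_GAMMA,
                            thickness: float = DEFAULT_THICKNESS,
                            label: str = "",
                            clamp: bool = False) -> ReleaseProfile:
    """Predict a full release profile at an unseen value of the varied factor.

    ``models`` maps constant names to fitted correlations and must cover
    ``k_b``, ``D_e`` and either ``k_os`` or ``delta_pi`` (converted through
    ``gamma``).  ``weight_source`` lists ``(factor_value, (μ_burst, μ_diff,
    μ_osm))`` pairs at the training conditions; weights at ``x`` are linearly
    interpolated and renormalized to the simplex.  The assembled parameter set
    is simulated forward with :func:`composite_release`.
    """
    for name in ("k_b", "D_e"):
        if name not in models:
            raise InputError(f"missing correlation model for {name}")
    k_b = predict_constant(models["k_b"], x)
    D_e = predict_constant(models["D_e"], x)
    if "k_os" in models:
        k_os = predict_constant(models["k_os"], x)
    elif "delta_pi" in models:
        k_os = osmotic_slope(gamma, max(predict_constant(models["delta_pi"], x), 0.0))
    else:
        raise InputError("missing correlation model for k_os or delta_pi")
    mu = _interp_weights(weight_source, x)
    params = CompositeParams(mu=mu, k_b=k_b, D_e=D_e, k_os=max(k_os, 0.0))
    return composite_release(params, times, thickness=thickness, clamp=clamp, label=label)
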