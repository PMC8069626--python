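"""Synthetic release-profile generator.

Emulates experimental cumulative-release curves of diclofenac epolamine from
polyurethane films: the composite three-mechanism forward model evaluated on
a time grid, plus i.i.d. additive Gaussian observation noise on the fraction
scale (negatives clipped to 0 by default; values slightly above 1 are kept,
as in real cumulative-release data).

Five built-in named conditions cover three drug loads (10/20/30 % w/w) at a
flow rate of 7.5 mL/s and three flow rates (0/7.5/23.5 mL/s) at 20 % load,
with mechanism weights, burst constants, effective diffusivities and osmotic
gradients from published fits; the osmotic gradient is converted to the
zero-order slope via the configurable factor γ (k_os = γ·Δπ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .mechanisms import (
    DEFAULT_GAMMA,
    DEFAULT_THICKNESS,
    CompositeParams,
    ReleaseProfile,
    composite_release,
    osmotic_slope,
)

__all__ = ["GeneratorConfig", "builtin_conditions", "condition_params", "generate_profile"]

# label -> (burst %, osmosis %, diffusion %, k_b [1/h], delta_pi [atm],
#           D_e [m^2/h], concentration [% w/w], flow [mL/s])
_CONDITIONS = {
    "PU-10%DE-Q7.5": (23.2, 11.1, 65.7, 1.5, 0.005, 1.1e-8, 10.0, 7.5),
    "PU-20%DE-Q7.5": (31.3, 12.8, 55.9, 2.5, 0.009, 1.62e-8, 20.0, 7.5),
    "PU-30%DE-Q7.5": (36.0, 14.7, 49.3, 3.4, 0.014, 1.96e-8, 30.0, 7.5),
    "PU-20%DE-Q0": (29.0, 9.0, 62.0, 1.7, 0.007, 8.7e-9, 20.0, 0.0),
    "PU-20%DE-Q23.5": (31.9, 14.6, 53.5, 3.9, 0.012, 2.77e-8, 20.0, 23.5),
}


def builtin_conditions(gamma: float = DEFAULT_GAMMA) -> pd.DataFrame:
    """Table of the five built-in conditions, one row per condition label.

    Columns: mechanism weights (fractions, rows of the source percentages
    ÷ 100), ``k_b`` (h⁻¹), ``D_e`` (m²/h), ``delta_pi`` (atm), the derived
    ``k_os = γ·Δπ`` (h⁻¹), and the condition factors ``concentration_pct``
    and ``flow_ml_s``.
    """
    rows = []
    for label, (b, o, d, kb, dpi, de, conc, flow) in _CONDITIONS.items():
        rows.append({
            "label": label,
            "mu_burst": b / 100.0,
            "mu_diffusion": d / 100.0,
            "mu_osmosis": o / 100.0,
            "k_b": kb,
            "D_e": de,
            "delta_pi": dpi,
            "k_os": osmotic_slope(gamma, dpi),
            "concentration_pct": conc,
            "flow_ml_s": flow,
        })
    return pd.DataFrame(rows).set_index("label")


def condition_params(label: str, gamma: float = DEFAULT_GAMMA) -> CompositeParams:
    """CompositeParams for a built-in condition label."""
    if label not in _CONDITIONS:
        raise InputError(
            f"unknown condition {label!r}; known: {', '.join(_CONDITIONS)}"
        )
    b, o, d, kb, dpi, de, *_ = _CONDITIONS[label]
    mu = np.array([b, d, o]) / 100.0
    mu = mu / mu.sum()  # source rows sum to 100 exactly; guard regardless
    return CompositeParams(mu=mu, k_b=kb, D_e=de, k_os=osmotic_slope(gamma, dpi))


@dataclass
class GeneratorConfig:
    """Configuration of :func:`generate_profile`.

    The default grid (0–100 h, 101 points) covers the burst-, osmosis- and
    diffusion-dominated regimes for the built-in kinetic constants; default
    observation noise sd is 0.01 on the fraction scale.
    """

    label: str = "PU-20%DE-Q7.5"
    params: Optional[CompositeParams] = None
    t_start: float = 0.0
    t_stop: float = 100.0
    n_points: int = 101
    noise_sd: float = 0.01
    seed: int = 0
    clip_negative: bool = True
    gamma: float = DEFAULT_GAMMA
    thickness: float = DEFAULT_THICKNESS

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        if self.n_points < 2 or self.t_stop <= self.t_start or self.t_start < 0:
            raise InputError("invalid time grid")


def generate_profile(config: GeneratorConfig) -> tuple[ReleaseProfile, dict]:
    """Generate one synthetic profile and its ground-truth record.

    Returns the (possibly noisy) profile together with a truth record carrying
    the generating parameters, grid, noise level and seed.
    """
    params = config.params if config.params is not None else condition_params(
        config.label, config.gamma
    )
    times = np.linspace(config.t_start, config.t_stop, config.n_points)
    clean = composite_release(params, times, thickness=config.thickness,
                              label=config.label)
    fractions = clean.fractions
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        fractions = fractions + rng.normal(0.0, config.noise_sd, size=times.size)
        if config.clip_negative:
            fractions = np.maximum(fractions, 0.0)
    profile = ReleaseProfile(times=times, fractions=fractions, label=config.label)
    truth = {
        "label": config.label,
        "params": params,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "gamma": config.gamma,
        "thickness": config.thickness,
    }
    return profile, truth
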