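"""Reading/writing release profiles (CSV), fit reports (JSON) and config (YAML).

Profile CSV dialect: comma-separated, dot decimal, UTF-8, mandatory header.
Columns are ``time_h,fraction_released`` or ``time_h,mass_mg`` (the latter is
normalized to fractions by the total loaded mass ``m_inf`` in mg, supplied by
the caller or config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError
from .fitting import FitResult, FitSettings
from .mechanisms import CompositeParams, ReleaseProfile

__all__ = [
    "read_profile_csv",
    "write_profile_csv",
    "FitReport",
    "load_config",
    "settings_digest",
]


def _package_version() -> str:
    try:
        return version("relmech")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


def read_profile_csv(path, m_inf: Optional[float] = None, label: str = "") -> ReleaseProfile:
    """Read a release profile from CSV.

    The header must be ``time_h,fraction_released`` or ``time_h,mass_mg``;
    with a mass column the total loaded mass ``m_inf`` (mg) is required and
    fractions are computed as mass/m_inf.  Validation errors name the
    offending data row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: not parseable as CSV ({exc})") from exc
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "time_h" not in cols:
        raise FormatError(f"{path}: missing required column 'time_h' (header found: {cols})")
    if "fraction_released" in cols:
        fractions = df["fraction_released"].to_numpy(dtype=float)
    elif "mass_mg" in cols:
        if m_inf is None:
            raise InputError(f"{path}: mass_mg column requires m_inf (total loaded mass, mg)")
        if not m_inf > 0:
            raise InputError("m_inf must be positive")
        fractions = df["mass_mg"].to_numpy(dtype=float) / m_inf
    else:
        raise FormatError(
            f"{path}: expected a 'fraction_released' or 'mass_mg' column (header found: {cols})"
        )
    times = df["time_h"].to_numpy(dtype=float)
    if times.size > 1:
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            raise InputError(
                f"{path}: times must be strictly increasing; violated at row {int(bad[0]) + 2}"
            )
    return ReleaseProfile(times=times, fractions=fractions, label=label or path.stem)


def write_profile_csv(profile: ReleaseProfile, path) -> None:
    """Write a profile as ``time_h,fraction_released`` CSV."""
    pd.DataFrame(
        {"time_h": profile.times, "fraction_released": profile.fractions}
    ).to_csv(path, index=False)


def settings_digest(settings: FitSettings) -> str:
    """Stable sha256 digest of the fit settings (provenance stamp)."""
    payload = {k: v for k, v in asdict(settings).items()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class FitReport:
    """Serializable record of a fit: result plus provenance.

    Round-trips losslessly through :meth:`to_dict`/:meth:`from_dict` (and the
    JSON file helpers).
    """

    params: dict
    contributions: dict
    delta_pi: Optional[float]
    gamma: Optional[float]
    rmse: float
    r_squared: float
    converged: bool
    n_starts_used: int
    objective: float
    input_file: str = ""
    settings_digest: str = ""
    software_version: str = ""
    seed: Optional[int] = None
    label: str = ""
    concentration_pct: Optional[float] = None
    flow_ml_s: Optional[float] = None
    start_table: Optional[list] = None

    @classmethod
    def from_result(cls, result: FitResult, *, input_file: str = "",
                    settings: Optional[FitSettings] = None,
                    seed: Optional[int] = None, label: str = "",
                    concentration_pct: Optional[float] = None,
                    flow_ml_s: Optional[float] = None) -> "FitReport":
        p = result.params
        return cls(
            params={
                "mu_burst": p.mu_burst,
                "mu_diffusion": p.mu_diffusion,
                "mu_osmosis": p.mu_osmosis,
                "k_b": p.k_b,
                "D_e": p.D_e,
                "k_os": p.k_os,
            },
            contributions=dict(result.contributions),
            delta_pi=result.delta_pi,
            gamma=result.gamma,
            rmse=result.rmse,
            r_squared=result.r_squared,
            converged=result.converged,
            n_starts_used=result.n_starts_used,
            objective=result.objective,
            input_file=str(input_file),
            settings_digest=settings_digest(settings) if settings is not None else "",
            software_version=_package_version(),
            seed=seed,
            label=label,
            concentration_pct=concentration_pct,
            flow_ml_s=flow_ml_s,
            start_table=(result.start_table.to_dict("records")
                         if result.start_table is not None else None),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FitReport":
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "FitReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def composite_params(self) -> CompositeParams:
        p = self.params
        return CompositeParams(
            mu=np.array([p["mu_burst"], p["mu_diffusion"], p["mu_osmosis"]]),
            k_b=p["k_b"], D_e=p["D_e"], k_os=p["k_os"],
        )


def load_config(path) -> dict:
    """Load a YAML config (geometry, gamma, bounds, m_inf...), empty dict if None."""
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return data
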