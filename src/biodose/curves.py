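"""Dose-response models for dicentric yields and the rho/theta parameterization.

A mixed neutron + gamma exposure produces dicentrics additively from each
component: the gamma (low-LET) response is linear-quadratic in dose while the
neutron (high-LET) response is linear,

    Y_gamma(D)       = Y0 + beta*D + gamma*D**2
    Y_n(D)           = Y0 + alpha*D
    Y_mixed(Dn, Dg)  = Y0 + alpha*Dn + beta*Dg + gamma*Dg**2  (one background)

with yields in dicentrics per cell.  The field composition is described
either by the neutron-to-gamma dose ratio rho = Dn/Dg in [0, inf) or by the
gamma dose fraction theta = Dg/(Dg + Dn) = 1/(rho + 1) in (0, 1]; theta is
the variable that carries the prior in the Bayesian estimators.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "CalibrationCurve",
    "AberrationSample",
    "DoseRatio",
    "theta_from_rho",
    "rho_from_theta",
    "yield_gamma",
    "yield_neutron",
    "yield_mixed",
]


def theta_from_rho(rho):
    """Gamma dose fraction theta = 1/(rho + 1) for a dose ratio rho >= 0."""
    rho = np.asarray(rho, dtype=float)
    if np.any(~np.isfinite(rho)) or np.any(rho < 0):
        raise DomainError(f"rho must be finite and >= 0, got {rho}")
    out = 1.0 / (rho + 1.0)
    return float(out) if out.ndim == 0 else out


def rho_from_theta(theta):
    """Neutron-to-gamma dose ratio rho = 1/theta - 1 for theta in (0, 1]."""
    theta = np.asarray(theta, dtype=float)
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0) or np.any(theta > 1):
        raise DomainError(f"theta must lie in (0, 1], got {theta}")
    out = 1.0 / theta - 1.0
    return float(out) if out.ndim == 0 else out


_SD_FIELDS = ("sd_y0", "sd_alpha", "sd_beta", "sd_gamma")


@dataclass(frozen=True)
class CalibrationCurve:
    """Dose-response coefficients, optionally with one-standard-deviation values.

    Parameters
    ----------
    y0 : float
        Background dicentric yield (dic/cell).
    alpha : float
        High-LET (neutron) linear coefficient (dic/cell/Gy).
    beta : float
        Low-LET (gamma) linear coefficient (dic/cell/Gy).
    gamma_coef : float
        Low-LET quadratic coefficient (dic/cell/Gy^2).
    sd_y0, sd_alpha, sd_beta, sd_gamma : float, optional
        One standard deviation of the corresponding coefficient.
    """

    y0: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    gamma_coef: float = 0.0
    sd_y0: float | None = None
    sd_alpha: float | None = None
    sd_beta: float | None = None
    sd_gamma: float | None = None
    name: str | None = field(default=None, compare=False)

    def __post_init__(self):
        for attr in ("y0", "alpha", "beta", "gamma_coef"):
            v = getattr(self, attr)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"curve coefficient {attr} must be finite and >= 0, got {v}")
        for attr in _SD_FIELDS:
            v = getattr(self, attr)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise DomainError(f"{attr} must be finite and >= 0, got {v}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {"y0": self.y0, "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma_coef}
        for attr in _SD_FIELDS:
            v = getattr(self, attr)
            if v is not None:
                d[attr] = v
        if self.name:
            d["name"] = self.name
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        known = {"y0", "alpha", "beta", "gamma", "gamma_coef", "name", *_SD_FIELDS}
        unknown = set(d) - known
        if unknown:
            raise DomainError(f"unknown curve keys: {sorted(unknown)}")
        if "gamma" in d:
            d["gamma_coef"] = d.pop("gamma")
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_csv(cls, path) -> "CalibrationCurve":
        """Load from a one-row CSV with headers y0, alpha, beta, gamma[, sd_*]."""
        df = pd.read_csv(path)
        if len(df) != 1:
            raise DomainError(f"curve CSV must have exactly one row, got {len(df)}")
        row = {k: v for k, v in df.iloc[0].items() if pd.notna(v)}
        return cls.from_dict(row)

    def to_csv(self, path) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, index=False)

    def replace(self, **kw) -> "CalibrationCurve":
        d = asdict(self)
        d.update(kw)
        return CalibrationCurve(**d)


def _check_dose(d, name="dose"):
    d = np.asarray(d, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise DomainError(f"{name} must be finite and >= 0")
    return d


def yield_gamma(d_gamma, curve: CalibrationCurve):
    """Gamma-ray dicentric yield Y0 + beta*D + gamma*D^2."""
    d = _check_dose(d_gamma, "d_gamma")
    out = curve.y0 + curve.beta * d + curve.gamma_coef * d * d
    return float(out) if out.ndim == 0 else out


def yield_neutron(d_n, curve: CalibrationCurve):
    """Neutron dicentric yield Y0 + alpha*D."""
    d = _check_dose(d_n, "d_n")
    out = curve.y0 + curve.alpha * d
    return float(out) if out.ndim == 0 else out


def yield_mixed(d_n, d_gamma, curve: CalibrationCurve, y0: float | None = None):
    """Mixed-field yield Y0 + alpha*Dn + beta*Dg + gamma*Dg^2.

    The additivity model carries a single background term; by default the
    curve's own ``y0`` (conventionally the gamma-curve background) is used,
    and a different shared background can be supplied via ``y0``.
    """
    dn = _check_dose(d_n, "d_n")
    dg = _check_dose(d_gamma, "d_gamma")
    bg = curve.y0 if y0 is None else float(y0)
    if bg < 0:
        raise DomainError("background y0 must be >= 0")
    out = bg + curve.alpha * dn + curve.beta * dg + curve.gamma_coef * dg * dg
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class AberrationSample:
    """Observed dicentric count ``u`` in ``w`` scored cells."""

    u: int
    w: int

    def __post_init__(self):
        if int(self.u) != self.u or self.u < 0:
            raise DomainError(f"dicentric count u must be a non-negative integer, got {self.u}")
        if int(self.w) != self.w or self.w < 1:
            raise DomainError(f"cell count w must be a positive integer, got {self.w}")
        object.__setattr__(self, "u", int(self.u))
        object.__setattr__(self, "w", int(self.w))

    @property
    def yf(self) -> float:
        """Dicentric frequency u/w (dic/cell)."""
        return self.u / self.w

    def to_dict(self) -> dict:
        return {"u": self.u, "w": self.w, "yf": self.yf}


@dataclass(frozen=True)
class DoseRatio:
    """Field composition as the pair (rho, theta) with theta = 1/(rho+1)."""

    rho: float
    theta: float

    @classmethod
    def from_rho(cls, rho: float) -> "DoseRatio":
        return cls(rho=float(rho), theta=theta_from_rho(rho))

    @classmethod
    def from_theta(cls, theta: float) -> "DoseRatio":
        return cls(rho=rho_from_theta(theta), theta=float(theta))

    def __post_init__(self):
        if abs(self.theta - 1.0 / (self.rho + 1.0)) > 1e-12 * max(1.0, self.theta):
            raise DomainError("rho and theta are inconsistent; use from_rho/from_theta")
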