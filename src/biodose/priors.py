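"""Prior densities for the gamma dose fraction theta on (0, 1).

Six families are provided.  Informative choices: a Gaussian in theta, a
"scaled" Gaussian (a Gaussian in rho = 1/theta - 1 expressed as a density in
theta, which carries a theta^-2 factor), and a Beta kernel.  Non-informative
choices: the simplified Beta kernel theta*(1-theta) (Beta(2,2) up to a
constant), a sigmoidal ramp 2/(1 + exp(-k*theta + l)) encoding "the gamma
fraction exceeds a threshold", and a constant.

Densities are exposed unnormalized, as the family formulas are written;
``normalization`` integrates the kernel over (0, 1) by adaptive quadrature
and ``pdf`` divides by it.  Evaluation is done in log space so that sharp
priors (sigma of order 1e-4) do not underflow.
"""

from __future__ import annotations

import json
import math
from abc import ABC, abstractmethod
from pathlib import Path

import numpy as np
from scipy import integrate
from scipy import stats

from .errors import ConfigurationError, DomainError

__all__ = [
    "ThetaPrior",
    "GaussianPrior",
    "ScaledGaussianPrior",
    "BetaPrior",
    "SimplifiedBetaPrior",
    "SigmoidalPrior",
    "ConstantPrior",
    "parse_prior",
    "gamma_prior_density",
    "moment_match_gamma",
]

_EPS = 1e-9  # open-interval quadrature endpoint offset


class ThetaPrior(ABC):
    """A prior density for theta in (0, 1)."""

    family: str = ""

    def __init__(self):
        self._norm: float | None = None

    # -- family-specific ---------------------------------------------------
    @abstractmethod
    def log_density(self, theta):
        """Unnormalized log density at theta (vectorized)."""

    @abstractmethod
    def params(self) -> dict:
        """Family hyperparameters as a flat dict."""

    def breakpoints(self) -> list[float]:
        """Interior theta values where quadrature should place nodes."""
        return []

    def central_theta(self) -> float:
        """A representative location of prior mass, used to size dose grids."""
        return 0.5

    # -- shared ------------------------------------------------------------
    @staticmethod
    def _check_theta(theta):
        t = np.asarray(theta, dtype=float)
        if np.any(t <= 0.0) or np.any(t >= 1.0):
            raise DomainError("theta must lie strictly inside (0, 1)")
        return t

    def density(self, theta):
        """Unnormalized density at theta."""
        t = self._check_theta(theta)
        out = np.exp(self.log_density(t))
        return float(out) if out.ndim == 0 else out

    def normalization(self) -> float:
        """Z = integral of the unnormalized density over (0, 1)."""
        if self._norm is None:
            pts = [p for p in self.breakpoints() if _EPS < p < 1 - _EPS]
            z, _ = integrate.quad(
                lambda t: math.exp(float(self.log_density(t))),
                _EPS, 1 - _EPS, points=pts or None, limit=200,
            )
            if not math.isfinite(z) or z <= 0:
                raise ConfigurationError(
                    f"{self.family} prior does not integrate to a positive finite value (Z={z})"
                )
            self._norm = z
        return self._norm

    def pdf(self, theta):
        """Normalized density on (0, 1)."""
        t = self._check_theta(theta)
        out = np.exp(self.log_density(t)) / self.normalization()
        return float(out) if out.ndim == 0 else out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, **self.params()}

    def __repr__(self):
        kv = ", ".join(f"{k}={v:g}" for k, v in self.params().items())
        return f"{type(self).__name__}({kv})"


class GaussianPrior(ThetaPrior):
    """Gaussian in theta: exp(-(theta - theta_hat)^2 / (2 sigma_theta^2))."""

    family = "gaussian"

    def __init__(self, theta_hat: float, sigma_theta: float):
        super().__init__()
        if not (0 < theta_hat < 1):
            raise ConfigurationError("theta_hat must be in (0, 1)")
        if sigma_theta <= 0:
            raise ConfigurationError("sigma_theta must be > 0")
        self.theta_hat = float(theta_hat)
        self.sigma_theta = float(sigma_theta)

    def log_density(self, theta):
        t = np.asarray(theta, dtype=float)
        s = self.sigma_theta
        return -0.5 * math.log(2 * math.pi) - math.log(s) - (t - self.theta_hat) ** 2 / (2 * s * s)

    def params(self):
        return {"theta_hat": self.theta_hat, "sigma_theta": self.sigma_theta}

    def breakpoints(self):
        s = self.sigma_theta
        return sorted({min(max(self.theta_hat + k * s, _EPS), 1 - _EPS) for k in (-8, -3, 0, 3, 8)})

    def central_theta(self):
        return self.theta_hat


class ScaledGaussianPrior(ThetaPrior):
    """Gaussian in rho = 1/theta - 1, written as a density in theta.

    p(theta) = 1/(sqrt(2 pi) sigma_rho theta^2)
               * exp(-((1/theta - 1) - rho_hat)^2 / (2 sigma_rho^2)).
    """

    family = "scaled_gaussian"

    def __init__(self, rho_hat: float, sigma_rho: float):
        super().__init__()
        if rho_hat < 0:
            raise ConfigurationError("rho_hat must be >= 0")
        if sigma_rho <= 0:
            raise ConfigurationError("sigma_rho must be > 0")
        self.rho_hat = float(rho_hat)
        self.sigma_rho = float(sigma_rho)

    def log_density(self, theta):
        t = np.asarray(theta, dtype=float)
        s = self.sigma_rho
        rho = 1.0 / t - 1.0
        return (
            -0.5 * math.log(2 * math.pi) - math.log(s) - 2.0 * np.log(t)
            - (rho - self.rho_hat) ** 2 / (2 * s * s)
        )

    def params(self):
        return {"rho_hat": self.rho_hat, "sigma_rho": self.sigma_rho}

    def breakpoints(self):
        pts = []
        for k in (-8, -3, 0, 3, 8):
            rho = self.rho_hat + k * self.sigma_rho
            if rho >= 0:
                pts.append(min(max(1.0 / (rho + 1.0), _EPS), 1 - _EPS))
        return sorted(set(pts))

    def central_theta(self):
        return 1.0 / (self.rho_hat + 1.0)


class BetaPrior(ThetaPrior):
    """Beta kernel theta^(k-1) * (1-theta)^(l-1), normalized numerically."""

    family = "beta"

    def __init__(self, k: float, l: float):
        super().__init__()
        if k <= 0 or l <= 0:
            raise ConfigurationError("Beta shape parameters must be > 0")
        self.k = float(k)
        self.l = float(l)

    @classmethod
    def from_mode_concentration(cls, mode: float, concentration: float) -> "BetaPrior":
        """Shape parameters placing the mode at ``mode`` with total
        concentration k + l = ``concentration`` (> 2)."""
        if not (0 < mode < 1):
            raise ConfigurationError("mode must be in (0, 1)")
        if concentration <= 2:
            raise ConfigurationError("concentration must be > 2 for an interior mode")
        c = float(concentration)
        return cls(k=mode * (c - 2) + 1, l=(1 - mode) * (c - 2) + 1)

    def log_density(self, theta):
        t = np.asarray(theta, dtype=float)
        return (self.k - 1) * np.log(t) + (self.l - 1) * np.log1p(-t)

    def params(self):
        return {"k": self.k, "l": self.l}

    def breakpoints(self):
        if self.k > 1 and self.l > 1:
            return [(self.k - 1) / (self.k + self.l - 2)]
        return []

    def central_theta(self):
        if self.k > 1 and self.l > 1:
            return (self.k - 1) / (self.k + self.l - 2)
        return self.k / (self.k + self.l)


class SimplifiedBetaPrior(BetaPrior):
    """The fixed kernel theta*(1-theta), i.e. Beta with k = l = 2."""

    family = "beta_simple"

    def __init__(self):
        super().__init__(k=2.0, l=2.0)

    def params(self):
        return {}


class SigmoidalPrior(ThetaPrior):
    """Monotone ramp p(theta) = 2 / (1 + exp(-k*theta + l)).

    With k > 0 the density rises around theta = l/k; ``from_threshold``
    places the half-maximum at a stated threshold with default steepness 50,
    encoding "the gamma fraction exceeds t".
    """

    family = "sigmoidal"
    DEFAULT_STEEPNESS = 50.0

    def __init__(self, k: float, l: float):
        super().__init__()
        if k == 0:
            raise ConfigurationError("sigmoidal steepness k must be nonzero")
        self.k = float(k)
        self.l = float(l)

    @classmethod
    def from_threshold(cls, threshold: float, steepness: float | None = None) -> "SigmoidalPrior":
        if not (0 < threshold < 1):
            raise ConfigurationError("threshold must be in (0, 1)")
        k = cls.DEFAULT_STEEPNESS if steepness is None else float(steepness)
        return cls(k=k, l=k * threshold)

    def log_density(self, theta):
        t = np.asarray(theta, dtype=float)
        # log(2) - log(1 + exp(-(k t - l))) computed stably
        x = self.k * t - self.l
        return math.log(2.0) - np.logaddexp(0.0, -x)

    def params(self):
        return {"k": self.k, "l": self.l}

    def breakpoints(self):
        t = self.l / self.k
        return [min(max(t, _EPS), 1 - _EPS)] if 0 < t < 1 else []

    def central_theta(self):
        t = self.l / self.k
        if 0 < t < 1:
            return 0.5 * (t + 1.0) if self.k > 0 else 0.5 * t
        return 0.5


class ConstantPrior(ThetaPrior):
    """Flat prior; the constant is immaterial after normalization."""

    family = "constant"

    def __init__(self, const: float = 1.0):
        super().__init__()
        if const <= 0:
            raise ConfigurationError("const must be > 0")
        self.const = float(const)

    def log_density(self, theta):
        t = np.asarray(theta, dtype=float)
        return np.full_like(t, math.log(self.const))

    def params(self):
        return {"const": self.const} if self.const != 1.0 else {}


_FAMILIES = {
    "gaussian": GaussianPrior,
    "scaled_gaussian": ScaledGaussianPrior,
    "beta": BetaPrior,
    "beta_simple": SimplifiedBetaPrior,
    "sigmoidal": SigmoidalPrior,
    "constant": ConstantPrior,
}


def prior_from_dict(d: dict) -> ThetaPrior:
    """Build a prior from {"family": ..., <hyperparameters>}; unknown keys rejected."""
    d = dict(d)
    try:
        family = d.pop("family")
    except KeyError:
        raise ConfigurationError("prior specification must carry a 'family' key") from None
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ConfigurationError(
            f"unknown prior family {family!r}; available: {sorted(_FAMILIES)}"
        ) from None
    if family == "sigmoidal" and "threshold" in d:
        threshold = d.pop("threshold")
        steepness = d.pop("steepness", None)
        if d:
            _reject(d)
        return SigmoidalPrior.from_threshold(threshold, steepness)
    try:
        return cls(**d)
    except TypeError as e:
        raise ConfigurationError(f"invalid hyperparameters for {family!r}: {e}") from None


def _reject(extra):
    raise ConfigurationError(f"unknown prior keys: {sorted(extra)}")


def parse_prior(spec) -> ThetaPrior:
    """Parse a prior from a ThetaPrior, dict, compact string or file path.

    Compact strings look like ``"gaussian:theta_hat=0.92,sigma_theta=0.02"``;
    file paths may point to JSON or YAML documents with the same keys.
    """
    if isinstance(spec, ThetaPrior):
        return spec
    if isinstance(spec, dict):
        return prior_from_dict(spec)
    if isinstance(spec, (str, Path)):
        p = Path(spec)
        if p.suffix.lower() in {".json", ".yaml", ".yml"} or p.is_file():
            text = p.read_text()
            if p.suffix.lower() in {".yaml", ".yml"}:
                import yaml

                return prior_from_dict(yaml.safe_load(text))
            return prior_from_dict(json.loads(text))
        if ":" in spec or "=" not in spec:
            family, _, rest = str(spec).partition(":")
            d: dict = {"family": family.strip()}
            if rest.strip():
                for item in rest.split(","):
                    k, _, v = item.partition("=")
                    if not _:
                        raise ConfigurationError(f"malformed prior item {item!r}")
                    d[k.strip()] = float(v)
            return prior_from_dict(d)
    raise ConfigurationError(f"cannot interpret prior specification {spec!r}")


# -- Gamma priors on calibration-curve coefficients --------------------------

def gamma_prior_density(lambda_val, k: float, z: float):
    """Gamma density lambda^(k-1) z^k / Gamma(k) * exp(-z lambda) on [0, inf)."""
    if k <= 0 or z <= 0:
        raise ConfigurationError("Gamma shape k and scale z must be > 0")
    lam = np.asarray(lambda_val, dtype=float)
    if np.any(lam < 0):
        raise DomainError("lambda must be >= 0")
    out = stats.gamma.pdf(lam, a=k, scale=1.0 / z)
    return float(out) if out.ndim == 0 else out


def moment_match_gamma(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape k, rate z) with the given mean and standard deviation:
    k = (mean/sd)^2, z = mean/sd^2."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("mean and sd must be > 0 for moment matching")
    return (mean / sd) ** 2, mean / sd**2
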