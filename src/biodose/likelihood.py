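"""Poisson likelihood machinery shared by all estimators.

The dicentric count u in w scored cells is Poisson with mean w*yf, where yf
is the model yield per cell.  Everything is computed in natural-log space
(the u! term via log-Gamma) so counts up to ~1e6 are safe, and the dose
likelihoods parameterized by the gamma fraction theta are thin wrappers that
express the partner dose through theta before evaluating the mixed yield:
for the gamma component Dn = Dg*(1-theta)/theta, for the neutron component
Dg = Dn*theta/(1-theta).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .curves import AberrationSample, CalibrationCurve
from .errors import DomainError

__all__ = [
    "log_poisson_likelihood",
    "log_likelihood_dgamma",
    "log_likelihood_dn",
    "saturated_log_likelihood",
]


def log_poisson_likelihood(u: int, w: int, yf_model):
    """log P(u | w, yf) = u*ln(w*yf) - w*yf - lnGamma(u+1).

    ``yf_model`` may be an array.  A zero model yield with u > 0 returns
    -inf (a non-finite sentinel rather than an error); u = 0 gives -w*yf.
    """
    if w < 1:
        raise DomainError("w must be >= 1")
    if u < 0:
        raise DomainError("u must be >= 0")
    yf = np.asarray(yf_model, dtype=float)
    if np.any(yf < 0):
        raise DomainError("model yield must be >= 0")
    mu = w * yf
    if u == 0:
        out = -mu
    else:
        with np.errstate(divide="ignore"):
            out = u * np.log(mu) - mu - gammaln(u + 1)
    return float(out) if out.ndim == 0 else out


def saturated_log_likelihood(u: int, w: int) -> float:
    """Maximum of the Poisson log likelihood over the model yield (at yf = u/w);
    used as a max-subtraction constant before exponentiation."""
    if u == 0:
        return 0.0
    return float(u * np.log(u) - u - gammaln(u + 1))


def _check_theta_open(theta):
    t = np.asarray(theta, dtype=float)
    if np.any(t <= 0.0) or np.any(t >= 1.0):
        raise DomainError("theta must lie strictly inside (0, 1)")
    return t


def log_likelihood_dgamma(d_gamma, theta, sample: AberrationSample,
                          curve: CalibrationCurve, y0: float | None = None):
    """Log likelihood of the gamma dose with the neutron dose expressed via theta.

    Broadcasts over ``d_gamma`` and ``theta``.
    """
    t = _check_theta_open(theta)
    dg = np.asarray(d_gamma, dtype=float)
    if np.any(dg < 0):
        raise DomainError("d_gamma must be >= 0")
    bg = curve.y0 if y0 is None else y0
    yf = bg + curve.alpha * dg * (1.0 - t) / t + curve.beta * dg + curve.gamma_coef * dg * dg
    return log_poisson_likelihood(sample.u, sample.w, yf)


def log_likelihood_dn(d_n, theta, sample: AberrationSample,
                      curve: CalibrationCurve, y0: float | None = None):
    """Log likelihood of the neutron dose with the gamma dose expressed via theta."""
    t = _check_theta_open(theta)
    dn = np.asarray(d_n, dtype=float)
    if np.any(dn < 0):
        raise DomainError("d_n must be >= 0")
    bg = curve.y0 if y0 is None else y0
    dg = dn * t / (1.0 - t)
    yf = bg + curve.alpha * dn + curve.beta * dg + curve.gamma_coef * dg * dg
    return log_poisson_likelihood(sample.u, sample.w, yf)
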