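"""Poisson maximum-likelihood fitting of calibration curves.

Counts at each calibration dose are Poisson with mean w * Y(d), where Y is
either linear (high-LET: Y0 + a*d) or linear-quadratic (low-LET:
Y0 + a*d + b*d^2).  Coefficients are constrained non-negative (box bounds),
standard deviations come from the inverse observed information (a central
finite-difference Hessian of the negative log likelihood at the optimum),
and ``compare_forms`` reports a plain AIC comparison of the two shapes —
deliberately nothing more sophisticated than that.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .curves import CalibrationCurve
from .errors import ConfigurationError, ConvergenceError, DomainError
from .likelihood import log_poisson_likelihood

__all__ = ["CurveFit", "fit_curve_mle", "compare_forms"]

_FORMS = ("linear", "linear_quadratic")


def _as_table(data) -> pd.DataFrame:
    """Coerce calibration data to a DataFrame with dose_gy, dicentrics, cells."""
    if isinstance(data, (str, Path)) or hasattr(data, "read"):
        df = pd.read_csv(data)
    elif isinstance(data, pd.DataFrame):
        df = data.copy()
    else:
        df = pd.DataFrame(list(data), columns=["dose_gy", "dicentrics", "cells"])
    missing = {"dose_gy", "dicentrics", "cells"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"calibration data lacks columns: {sorted(missing)}")
    if (df["dose_gy"] < 0).any() or (df["dicentrics"] < 0).any() or (df["cells"] < 1).any():
        raise DomainError("doses/counts must be >= 0 and cells >= 1")
    return df


@dataclass
class CurveFit:
    """Result of a Poisson maximum-likelihood curve fit."""

    curve: CalibrationCurve
    form: str
    params: np.ndarray
    sds: np.ndarray
    loglik: float
    n_obs: int
    converged: bool
    at_boundary: bool
    cov: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * len(self.params) - 2.0 * self.loglik

    def summary(self) -> str:
        names = (["y0", "alpha"] if self.form == "linear"
                 else ["y0", "beta", "gamma"])
        lines = [f"Poisson MLE calibration fit ({self.form})",
                 "-" * 40]
        for name, p, s in zip(names, self.params, self.sds):
            lines.append(f"{name:<8}{p:>12.6f} +/- {s:.6f}")
        lines.append(f"{'loglik':<8}{self.loglik:>12.4f}   AIC {self.aic:.4f}")
        if self.at_boundary:
            lines.append("note: optimum on the non-negativity boundary")
        return "\n".join(lines)


def _nll_factory(df: pd.DataFrame, form: str):
    d = df["dose_gy"].to_numpy(float)
    u = df["dicentrics"].to_numpy(float)
    w = df["cells"].to_numpy(float)

    def yields(p):
        if form == "linear":
            return p[0] + p[1] * d
        return p[0] + p[1] * d + p[2] * d * d

    def nll(p):
        yf = yields(p)
        if np.any(yf < 0):
            return 1e12
        mu = w * yf
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(u > 0,
                             u * np.log(np.maximum(mu, 1e-300)) - mu,
                             -mu)
        if np.any(np.isneginf(terms)):
            return 1e12
        return -float(terms.sum())

    return nll, (d, u, w)


def _numeric_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = np.maximum(np.abs(x) * rel_step, 1e-8)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


def fit_curve_mle(data, form: str = "linear_quadratic") -> CurveFit:
    """Fit (y0, alpha) or (y0, beta, gamma) by Poisson maximum likelihood.

    ``data`` is a DataFrame / CSV path / iterable of (dose_gy, dicentrics,
    cells) rows.  Requires at least 3 distinct doses for the linear form and
    4 for the linear-quadratic.  The returned :class:`CurveFit` carries the
    coefficients as a :class:`CalibrationCurve` (linear fits fill ``alpha``,
    linear-quadratic fits fill ``beta``/``gamma``) with standard deviations
    from the inverse observed information.
    """
    if form not in _FORMS:
        raise ConfigurationError(f"form must be one of {_FORMS}")
    df = _as_table(data)
    n_distinct = df["dose_gy"].nunique()
    n_min = 3 if form == "linear" else 4
    if n_distinct < n_min:
        raise ConfigurationError(
            f"{form} fit needs >= {n_min} distinct doses, got {n_distinct}"
        )
    nll, (d, u, w) = _nll_factory(df, form)

    # start from a clipped least-squares fit of the raw frequencies
    deg = 1 if form == "linear" else 2
    freq = u / w
    coeffs = np.polynomial.polynomial.polyfit(d, freq, deg)
    x0 = np.clip(coeffs, 1e-6, None)

    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            bounds=[(0.0, None)] * len(x0))
    if not res.success and res.fun >= 1e11:
        raise ConvergenceError(f"curve fit failed: {res.message}", trajectory=[list(x0)])
    p = res.x
    at_boundary = bool(np.any(p <= 1e-12))

    H = _numeric_hessian(nll, np.maximum(p, 1e-10))
    try:
        cov = np.linalg.inv(H)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        cov, sds = None, np.full_like(p, np.nan)

    ll = float(sum(log_poisson_likelihood(int(ui), int(wi), yfi)
                   for ui, wi, yfi in zip(u, w, _model_yields(p, d, form))))
    if form == "linear":
        curve = CalibrationCurve(y0=p[0], alpha=p[1],
                                 sd_y0=_sd(sds, 0), sd_alpha=_sd(sds, 1))
    else:
        curve = CalibrationCurve(y0=p[0], beta=p[1], gamma_coef=p[2],
                                 sd_y0=_sd(sds, 0), sd_beta=_sd(sds, 1),
                                 sd_gamma=_sd(sds, 2))
    return CurveFit(curve=curve, form=form, params=p, sds=sds, loglik=ll,
                    n_obs=len(df), converged=bool(res.success),
                    at_boundary=at_boundary, cov=cov)


def _sd(sds, i):
    v = sds[i]
    return float(v) if np.isfinite(v) else None


def _model_yields(p, d, form):
    if form == "linear":
        return p[0] + p[1] * d
    return p[0] + p[1] * d + p[2] * d * d


def compare_forms(data, delta_aic_tie: float = 2.0) -> dict:
    """Fit both curve shapes and report a plain AIC preference.

    Returns ``{"loglik_linear", "loglik_lq", "aic_linear", "aic_lq",
    "preferred"}`` where ``preferred`` is ``"indeterminate"`` when the AIC
    difference is below ``delta_aic_tie``.
    """
    fit_lin = fit_curve_mle(data, "linear")
    fit_lq = fit_curve_mle(data, "linear_quadratic")
    delta = fit_lin.aic - fit_lq.aic
    if abs(delta) < delta_aic_tie:
        preferred = "indeterminate"
    else:
        preferred = "linear_quadratic" if delta > 0 else "linear"
    return {
        "loglik_linear": fit_lin.loglik,
        "loglik_lq": fit_lq.loglik,
        "aic_linear": fit_lin.aic,
        "aic_lq": fit_lq.aic,
        "preferred": preferred,
        "fits": {"linear": fit_lin, "linear_quadratic": fit_lq},
    }
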