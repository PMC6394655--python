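"""Classical mixed-field dose partitioning with a known dose ratio rho.

With rho = Dn/Dg fixed, the mixed-field yield equation

    y_f = y0 + alpha*rho*Dg + beta*Dg + gamma*Dg**2

is a quadratic in the gamma dose.  ``solve_analytical`` takes its positive
root directly; ``solve_iterative`` reaches the same point by the classical
subtraction scheme that alternates between attributing yield to one
component and re-estimating the other.  The naive substitution order
(all yield to neutrons first) is a fixed-point map whose slope is
-(beta + 2*gamma*Dg)/(alpha*rho); whenever the gamma response dominates the
yield gradient that map diverges, so the solver picks the direction whose
map is contractive (the two slopes are reciprocal, hence exactly one
direction converges away from |slope| = 1).
"""

from __future__ import annotations

import math

import numpy as np

from .curves import AberrationSample, CalibrationCurve, yield_mixed
from .errors import (
    BelowBackgroundError,
    ConvergenceError,
    DomainError,
    InfeasibleInputError,
)
from .results import MixedDoseResult

__all__ = ["solve_analytical", "solve_iterative", "propagate_uncertainty_classical"]


def _gamma_dose_root(excess: float, b: float, a: float) -> float:
    """Nonnegative root of a*D^2 + b*D - excess = 0 (excess >= 0)."""
    if excess <= 0:
        return 0.0
    if a > 0:
        disc = b * b + 4.0 * a * excess
        return (-b + math.sqrt(disc)) / (2.0 * a)
    if b > 0:
        return excess / b
    raise InfeasibleInputError(
        "yield exceeds background but every dose coefficient is zero"
    )


def _validate(sample: AberrationSample, rho: float, curve: CalibrationCurve,
              y0: float | None) -> tuple[float, float]:
    if not math.isfinite(rho) or rho < 0:
        raise DomainError(f"rho must be finite and >= 0, got {rho}")
    bg = curve.y0 if y0 is None else float(y0)
    excess = sample.yf - bg
    if excess < 0:
        raise BelowBackgroundError(
            f"observed frequency {sample.yf:.6g} is below background {bg:.6g}"
        )
    return bg, excess


def solve_analytical(sample: AberrationSample, rho: float, curve: CalibrationCurve,
                     *, y0: float | None = None, sd_rho: float | None = None
                     ) -> MixedDoseResult:
    """Closed-form gamma/neutron doses for a known ratio rho.

    Solves gamma*Dg^2 + (beta + alpha*rho)*Dg - (y_f - y0) = 0 on the
    positive branch (linear fallback when the quadratic term vanishes) and
    sets Dn = rho*Dg.  Uncertainties, when curve standard deviations are
    available, come from :func:`propagate_uncertainty_classical`.
    """
    bg, excess = _validate(sample, rho, curve, y0)
    b = curve.beta + curve.alpha * rho
    d_gamma = _gamma_dose_root(excess, b, curve.gamma_coef)
    d_n = rho * d_gamma
    sd_g, sd_n, unc = propagate_uncertainty_classical(
        sample, rho, curve, sd_rho=sd_rho, y0=y0
    )
    return MixedDoseResult(
        d_gamma=d_gamma, d_n=d_n, sd_gamma=sd_g, sd_n=sd_n,
        method="analytical",
        diagnostics={"rho": rho, "residual": yield_mixed(d_n, d_gamma, curve, y0=bg) - sample.yf,
                     "uncertainty": unc["label"], "uncertainty_components": unc["components"]},
    )


def solve_iterative(sample: AberrationSample, rho: float, curve: CalibrationCurve,
                    *, y0: float | None = None, tol: float = 1e-6,
                    max_iter: int = 500, sd_rho: float | None = None
                    ) -> MixedDoseResult:
    """Iterative subtraction scheme for a known ratio rho.

    Alternates between the two components until successive neutron doses
    change by less than ``tol`` (relative).  See the module docstring for
    the direction choice.
    """
    bg, excess = _validate(sample, rho, curve, y0)
    al, be, ga = curve.alpha, curve.beta, curve.gamma_coef

    if excess == 0.0:
        return _iterative_result(sample, 0.0, rho, curve, bg, 0, True, [0.0],
                                 sd_rho=sd_rho, y0=y0)
    if rho == 0.0 or al == 0.0:
        # pure-gamma route: no neutron yield to subtract
        d_gamma = _gamma_dose_root(excess, be, ga)
        return _iterative_result(sample, d_gamma, rho, curve, bg, 1, True,
                                 [rho * d_gamma], sd_rho=sd_rho, y0=y0)
    if be == 0.0 and ga == 0.0:
        d_gamma = excess / (al * rho)
        return _iterative_result(sample, d_gamma, rho, curve, bg, 1, True,
                                 [rho * d_gamma], sd_rho=sd_rho, y0=y0)

    # contraction test at the all-gamma first guess
    d_tilde = _gamma_dose_root(excess, be, ga)
    slope_gamma_update = al * rho / (be + 2.0 * ga * d_tilde) if (be + 2 * ga * d_tilde) > 0 else math.inf

    # Both update maps have negative slope at the solution, so an
    # under-relaxed step (weight 0.5 on the raw update) is applied: it
    # damps the alternation and prevents the 2-cycle the raw subtraction
    # scheme falls into when the first attribution overshoots.
    relax = 0.5
    traj: list[float] = []
    converged = False
    if slope_gamma_update <= 1.0:
        # start from the all-gamma attribution; subtract the neutron yield
        d_gamma = d_tilde
        d_n = rho * d_gamma
        traj.append(d_n)
        for it in range(1, max_iter + 1):
            neutron_yield = al * d_n
            d_gamma_raw = _gamma_dose_root(max(excess - neutron_yield, 0.0), be, ga)
            d_gamma_new = (1.0 - relax) * d_gamma + relax * d_gamma_raw
            d_n_new = rho * d_gamma_new
            traj.append(d_n_new)
            if abs(d_n_new - d_n) <= tol * max(abs(d_n_new), 1e-300):
                d_gamma, d_n, converged = d_gamma_new, d_n_new, True
                break
            d_gamma, d_n = d_gamma_new, d_n_new
    else:
        # start from the all-neutron attribution; subtract the gamma yield
        d_n = excess / al
        traj.append(d_n)
        d_gamma = d_n / rho
        for it in range(1, max_iter + 1):
            gamma_yield = be * d_gamma + ga * d_gamma * d_gamma
            d_n_raw = max(excess - gamma_yield, 0.0) / al
            d_n_new = (1.0 - relax) * d_n + relax * d_n_raw
            traj.append(d_n_new)
            if abs(d_n_new - d_n) <= tol * max(abs(d_n_new), 1e-300):
                d_n, converged = d_n_new, True
                d_gamma = d_n / rho
                break
            d_n = d_n_new
            d_gamma = d_n / rho
    if not converged:
        raise ConvergenceError(
            f"iterative solver did not converge in {max_iter} iterations", trajectory=traj
        )
    return _iterative_result(sample, d_gamma, rho, curve, bg, it, converged, traj,
                             sd_rho=sd_rho, y0=y0)


def _iterative_result(sample, d_gamma, rho, curve, bg, n_iter, converged, traj,
                      *, sd_rho, y0):
    d_n = rho * d_gamma
    sd_g, sd_n, unc = propagate_uncertainty_classical(
        sample, rho, curve, sd_rho=sd_rho, y0=y0
    )
    return MixedDoseResult(
        d_gamma=d_gamma, d_n=d_n, sd_gamma=sd_g, sd_n=sd_n, method="iterative",
        diagnostics={"rho": rho, "n_iter": n_iter, "converged": converged,
                     "trajectory": traj[-5:], "uncertainty": unc["label"],
                     "uncertainty_components": unc["components"]},
    )


def propagate_uncertainty_classical(sample: AberrationSample, rho: float,
                                    curve: CalibrationCurve, *,
                                    sd_rho: float | None = None,
                                    y0: float | None = None):
    """Independent-finite-increments uncertainty of the classical solution.

    Each input (the count u via its Poisson sd sqrt(u), each curve
    coefficient with a stated sd, and rho when ``sd_rho`` is given) is
    perturbed by +/- one sd, the solve is repeated, and the half-range dose
    shifts are combined in quadrature.  Returns ``(sd_gamma, sd_n, info)``
    where ``info['label']`` is ``'finite_increments'`` or
    ``'poisson_only'`` when no coefficient sds are available.
    """
    bg = curve.y0 if y0 is None else float(y0)

    def _solve(u_val, al, be, ga, bg_val, rho_val):
        excess = u_val / sample.w - bg_val
        if excess < 0:
            excess = 0.0
        rho_val = max(rho_val, 0.0)
        b = be + al * rho_val
        dg = _gamma_dose_root(excess, b, ga)
        return dg, rho_val * dg

    base = _solve(sample.u, curve.alpha, curve.beta, curve.gamma_coef, bg, rho)
    sd_u = math.sqrt(sample.u) if sample.u > 0 else 1.0
    have_curve_sds = False
    param_order = ["alpha", "beta", "gamma_coef", "y0"]
    sd_map = {"alpha": curve.sd_alpha, "beta": curve.sd_beta,
              "gamma_coef": curve.sd_gamma, "y0": curve.sd_y0}

    def _args(u_val=None, **over):
        vals = {"alpha": curve.alpha, "beta": curve.beta,
                "gamma_coef": curve.gamma_coef, "y0": bg, "rho": rho}
        vals.update(over)
        return (sample.u if u_val is None else u_val, vals["alpha"], vals["beta"],
                vals["gamma_coef"], vals["y0"], vals["rho"])

    comps: dict[str, tuple[float, float]] = {}
    var_g = var_n = 0.0

    def _add(name, args_hi, args_lo):
        nonlocal var_g, var_n
        hi = _solve(*args_hi)
        lo = _solve(*args_lo)
        dg = 0.5 * abs(hi[0] - lo[0])
        dn = 0.5 * abs(hi[1] - lo[1])
        comps[name] = (dg, dn)
        var_g += dg * dg
        var_n += dn * dn

    _add("u", _args(u_val=sample.u + sd_u), _args(u_val=max(sample.u - sd_u, 0.0)))
    for p in param_order:
        sd = sd_map[p]
        if sd is not None and sd > 0:
            have_curve_sds = True
            base_val = {"alpha": curve.alpha, "beta": curve.beta,
                        "gamma_coef": curve.gamma_coef, "y0": bg}[p]
            _add(p, _args(**{p: base_val + sd}), _args(**{p: max(base_val - sd, 0.0)}))
    if sd_rho is not None and sd_rho > 0:
        have_curve_sds = True
        _add("rho", _args(rho=rho + sd_rho), _args(rho=max(rho - sd_rho, 0.0)))

    label = "finite_increments" if have_curve_sds else "poisson_only"
    info = {"label": label, "components": {k: list(v) for k, v in comps.items()},
            "base": list(base)}
    return math.sqrt(var_g), math.sqrt(var_n), info
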