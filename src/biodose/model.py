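"""Model front-end tying the estimators together.

``MixedFieldModel`` holds one aberration sample and one calibration curve;
``fit`` dispatches to the classical solvers (known ratio) or the Bayesian
estimators (ratio prior) and returns a :class:`~biodose.results.MixedDoseResult`.

    >>> from biodose import MixedFieldModel, load_curve, GaussianPrior
    >>> model = MixedFieldModel.from_counts(35, 500, load_curve("clor_bm"))
    >>> res = model.fit(method="bayes", prior=GaussianPrior(0.92, 0.02))
    >>> print(res.summary())                                # doctest: +SKIP
"""

from __future__ import annotations

import pandas as pd

from . import bayes, bayes_full, classical
from .curves import AberrationSample, CalibrationCurve
from .errors import ConfigurationError
from .priors import parse_prior
from .results import MixedDoseResult

__all__ = ["MixedFieldModel"]

_ALIASES = {
    "iterative": "iterative",
    "analytical": "analytical",
    "bayes": "bayes_simplified",
    "bayes_simplified": "bayes_simplified",
    "bayes-simplified": "bayes_simplified",
    "bayes_full": "bayes_full",
    "bayes-full": "bayes_full",
}


class MixedFieldModel:
    """A dicentric sample paired with a mixed-field calibration curve."""

    def __init__(self, sample: AberrationSample, curve: CalibrationCurve, *,
                 y0: float | None = None):
        if not isinstance(sample, AberrationSample):
            raise ConfigurationError("sample must be an AberrationSample")
        if not isinstance(curve, CalibrationCurve):
            raise ConfigurationError("curve must be a CalibrationCurve")
        self.sample = sample
        self.curve = curve
        self.y0 = y0

    @classmethod
    def from_counts(cls, u: int, w: int, curve: CalibrationCurve, **kw) -> "MixedFieldModel":
        return cls(AberrationSample(u=u, w=w), curve, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, curve: CalibrationCurve, **kw) -> "MixedFieldModel":
        """Build from a one-row DataFrame with 'dicentrics' and 'cells' columns."""
        if len(df) != 1:
            raise ConfigurationError("expected exactly one sample row")
        row = df.iloc[0]
        return cls.from_counts(int(row["dicentrics"]), int(row["cells"]), curve, **kw)

    def fit(self, method: str = "bayes", *, rho: float | None = None,
            sd_rho: float | None = None, prior=None,
            grid: bayes.GridSpec | None = None, tol: float = 1e-6,
            max_iter: int = 500, integrator: str = "quad",
            n_nodes: int = 24, theta_nodes: int = 48,
            n_draws: int = 200_000, seed: int | None = None) -> MixedDoseResult:
        """Estimate the gamma and neutron dose components.

        ``method`` is one of ``iterative``/``analytical`` (both need
        ``rho``) or ``bayes``/``bayes_full`` (both need ``prior``, given as
        a :class:`~biodose.priors.ThetaPrior`, a dict, a compact string or
        a file path).
        """
        try:
            method = _ALIASES[method]
        except KeyError:
            raise ConfigurationError(
                f"unknown method {method!r}; available: {sorted(set(_ALIASES.values()))}"
            ) from None
        if method in ("iterative", "analytical"):
            if rho is None:
                raise ConfigurationError(f"{method} method requires rho")
            if method == "analytical":
                return classical.solve_analytical(self.sample, rho, self.curve,
                                                  y0=self.y0, sd_rho=sd_rho)
            return classical.solve_iterative(self.sample, rho, self.curve,
                                             y0=self.y0, tol=tol,
                                             max_iter=max_iter, sd_rho=sd_rho)
        if prior is None:
            raise ConfigurationError(f"{method} method requires a theta prior")
        prior = parse_prior(prior)
        if method == "bayes_simplified":
            return bayes.estimate_pair(self.sample, self.curve, prior, grid, y0=self.y0)
        return bayes_full.estimate_pair_full(
            self.sample, self.curve, prior, grid, y0=self.y0,
            integrator=integrator, n_nodes=n_nodes, theta_nodes=theta_nodes,
            n_draws=n_draws, seed=seed,
        )

    def __repr__(self):
        return (f"MixedFieldModel(u={self.sample.u}, w={self.sample.w}, "
                f"curve={self.curve.name or self.curve.to_dict()})")
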