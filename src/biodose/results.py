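"""Common result container for all mixed-field dose estimators."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

from .errors import DomainError

__all__ = ["MixedDoseResult"]

_METHODS = {"iterative", "analytical", "bayes_simplified", "bayes_full", "multi_field"}


@dataclass
class MixedDoseResult:
    """Paired (D_gamma, D_n) estimates with uncertainties and diagnostics.

    ``sd_gamma``/``sd_n`` are NaN when no uncertainty could be attached (for
    instance a posterior mode on the boundary).  ``diagnostics`` carries
    method-specific material: iteration counts and convergence flags for the
    classical solvers, posterior summaries for the Bayesian ones.
    """

    d_gamma: float
    d_n: float
    sd_gamma: float = math.nan
    sd_n: float = math.nan
    method: str = "analytical"
    diagnostics: dict[str, Any] = field(default_factory=dict)
    posteriors: dict[str, Any] | None = None

    def __post_init__(self):
        if self.method not in _METHODS:
            raise DomainError(f"unknown method tag {self.method!r}")
        for name in ("d_gamma", "d_n"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {v}")
        for name in ("sd_gamma", "sd_n"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise DomainError(f"{name} must be >= 0 or NaN, got {v}")

    @property
    def d_total(self) -> float:
        return self.d_gamma + self.d_n

    def to_dict(self) -> dict:
        d = {
            "d_gamma": self.d_gamma,
            "d_n": self.d_n,
            "sd_gamma": self.sd_gamma,
            "sd_n": self.sd_n,
            "method": self.method,
        }
        diag = {k: v for k, v in self.diagnostics.items()
                if isinstance(v, (int, float, str, bool, list, dict, type(None)))}
        d["diagnostics"] = diag
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Mixed-field dose estimate",
            "=" * 46,
            f"{'method':<22}{self.method}",
            f"{'D_gamma [Gy]':<22}{self.d_gamma:.4f} +/- {self.sd_gamma:.4f}",
            f"{'D_n     [Gy]':<22}{self.d_n:.4f} +/- {self.sd_n:.4f}",
            f"{'D_total [Gy]':<22}{self.d_total:.4f}",
        ]
        for key in ("rho", "n_iter", "converged", "prior", "uncertainty"):
            if key in self.diagnostics:
                lines.append(f"{key:<22}{self.diagnostics[key]}")
        if self.posteriors:
            for comp, post in self.posteriors.items():
                lo, hi = post.credible_interval
                lines.append(
                    f"{comp + ' 95% CrI [Gy]':<22}({lo:.4f}, {hi:.4f})"
                )
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot_posteriors(self, ax=None):
        """Plot the dose posteriors (Bayesian methods only)."""
        if not self.posteriors:
            raise ValueError("no posteriors attached to this result")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for comp, post in self.posteriors.items():
            post.plot(ax=ax, label=comp)
        ax.legend()
        return ax
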