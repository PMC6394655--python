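"""Named calibration-curve fixtures used throughout the examples and tests.

``silene`` is the curve for the SILENE reactor criticality-pulse experiment
(background zero, coefficients with standard deviations).  The ``clor_*``
curves are the CLOR laboratory fits for the MARIA reactor experiment: a
neutron curve, a Co-60 gamma curve and a mixed-field curve, each fitted by
two routes (a robust Bayesian fit, ``bm``, and plain maximum likelihood,
``mle``).
"""

from __future__ import annotations

from .curves import CalibrationCurve

SILENE = CalibrationCurve(
    y0=0.0,
    alpha=0.835,
    beta=0.0142,
    gamma_coef=0.0759,
    sd_alpha=0.098,
    sd_beta=0.0098,
    sd_gamma=0.0126,
    name="silene",
)

# CLOR gamma (Co-60) curve; alpha carried from the CLOR neutron curve so a
# single object supports the mixed-field model (shared background: gamma y0).
CLOR_BM = CalibrationCurve(
    y0=0.0010,
    alpha=0.354,
    beta=0.011,
    gamma_coef=0.056,
    sd_y0=0.0001,
    sd_alpha=0.002,
    sd_beta=0.001,
    sd_gamma=0.001,
    name="clor_bm",
)

CLOR_MLE = CalibrationCurve(
    y0=0.0010,
    alpha=0.354,
    beta=0.012,
    gamma_coef=0.056,
    sd_y0=0.0040,
    sd_alpha=0.003,
    sd_beta=0.003,
    sd_gamma=0.002,
    name="clor_mle",
)

CLOR_NEUTRON_BM = CalibrationCurve(
    y0=0.0005, alpha=0.354, sd_y0=0.0001, sd_alpha=0.002, name="clor_neutron_bm"
)
CLOR_NEUTRON_MLE = CalibrationCurve(
    y0=0.0005, alpha=0.354, sd_y0=0.0001, sd_alpha=0.003, name="clor_neutron_mle"
)

CLOR_MIXED_BM = CalibrationCurve(
    y0=0.0010, beta=0.038, gamma_coef=0.048,
    sd_y0=0.0001, sd_beta=0.001, sd_gamma=0.002, name="clor_mixed_bm",
)
CLOR_MIXED_MLE = CalibrationCurve(
    y0=0.0010, beta=0.038, gamma_coef=0.048,
    sd_y0=0.0001, sd_beta=0.004, sd_gamma=0.003, name="clor_mixed_mle",
)

_REGISTRY = {
    "silene": SILENE,
    "clor_bm": CLOR_BM,
    "clor_mle": CLOR_MLE,
    "clor_neutron_bm": CLOR_NEUTRON_BM,
    "clor_neutron_mle": CLOR_NEUTRON_MLE,
    "clor_mixed_bm": CLOR_MIXED_BM,
    "clor_mixed_mle": CLOR_MIXED_MLE,
}


def load_curve(name: str) -> CalibrationCurve:
    """Return a packaged calibration curve by name.

    Available names: silene, clor_bm, clor_mle, clor_neutron_bm,
    clor_neutron_mle, clor_mixed_bm, clor_mixed_mle.
    """
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown curve {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_curves() -> list[str]:
    return sorted(_REGISTRY)
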