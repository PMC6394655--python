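# Methods

## Model and assumptions

Dicentric production is assumed additive across field components and
Poisson-distributed across cells: the count `u` in `w` scored cells has
mean `w * y_f` with

    y_f(D_n, D_gamma) = Y0 + alpha*D_n + beta*D_gamma + gamma*D_gamma^2 .

The model carries a *single* background term. Laboratories typically fit a
separate background per curve; here the mixed-field equation uses one `Y0`
(by convention the gamma-curve background, overridable via the `y0`
argument everywhere). Doses are absorbed doses in Gy throughout; a kerma
fraction supplied by physical dosimetry is used directly as the dose
fraction, with no kerma-to-dose conversion. No dose-rate (G-function)
corrections and no overdispersion: the likelihood is exactly Poisson.

The field composition enters either as a known ratio `rho = D_n/D_gamma`
(classical solvers) or as a prior on the gamma fraction
`theta = 1/(rho+1)` (Bayesian solvers). `theta` is the integration
variable because it is bounded on (0, 1).

## Classical solvers

With `rho` fixed the yield equation is
`gamma*Dg^2 + (beta + alpha*rho)*Dg - (y_f - Y0) = 0`; the analytical
solver takes the positive branch (linear fallback when `gamma = 0`).
Samples with `y_f < Y0` are rejected rather than clamped — a below-background
frequency signals bad inputs, and silently returning zero would hide it.

The iterative solver implements the classical subtraction scheme:
attribute the yield to one component, convert through `rho`, subtract that
component's yield, re-estimate, repeat. Written as a fixed-point map in the
neutron dose its slope at the solution is
`-(beta + 2*gamma*Dg)/(alpha*rho)`; the reciprocal map (updating the gamma
dose) has the inverse slope, so exactly one direction is contractive. The
solver tests the slope at the all-gamma first attribution and iterates the
contractive direction, with an under-relaxed step (weight 0.5) that
suppresses the alternating overshoot the raw scheme exhibits when the first
attribution is far off. Defaults: relative tolerance 1e-6 on `D_n`,
`max_iter = 500`. The converged result agrees with the closed form to well
within 10x the tolerance (property-tested on random feasible inputs).

Classical uncertainties use independent finite increments: the count
(`+/- sqrt(u)`), each coefficient with a stated sd, and optionally `rho`
are perturbed one at a time by one sd, the solve is repeated, and the
half-range dose shifts add in quadrature. When no coefficient sds are
available the result is flagged `poisson_only`.

## Priors on the gamma fraction

Six families, all normalized numerically on (0, 1):

| family | kernel | intended use |
|---|---|---|
| `gaussian(theta_hat, sigma_theta)` | `exp(-(t-that)^2/2s^2)` | fraction measured with symmetric error |
| `scaled_gaussian(rho_hat, sigma_rho)` | `t^-2 exp(-((1/t-1)-rhat)^2/2s^2)` | ratio measured with symmetric error |
| `beta(k, l)` | `t^(k-1)(1-t)^(l-1)` | asymmetric knowledge (criticality scenarios) |
| `beta_simple` | `t(1-t)` | "comparable contributions", weakly informative |
| `sigmoidal(k, l)` | `2/(1+exp(-kt+l))` | "fraction exceeds a threshold" |
| `constant` | `1` | no information (academic baseline) |

Notes on choices that were genuinely open:

* The Beta family is implemented as its kernel and normalized numerically,
  so any printed normalization constant is irrelevant to results.
* A helper maps (mode m, concentration c) to Beta shapes
  `k = m(c-2)+1, l = (1-m)(c-2)+1` for users who think in those terms.
* The sigmoidal default places the half-maximum at a stated threshold `t`
  (`l = k*t`) with steepness `k = 50` — sharp enough to read as a
  threshold, smooth enough for stable quadrature. Published analyses using
  sigmoidal priors rarely state their shape parameters, so sigmoidal
  results are comparable only qualitatively.
* Densities are evaluated in log space; a Gaussian prior with
  `sigma_theta = 1e-4` neither underflows nor gets missed by quadrature,
  because every family exposes breakpoints that split the integration
  interval around its mass.

The constant prior's constant is immaterial after normalization. Priors on
curve coefficients (full-Bayes, multi-field) are Gamma with moment-matched
shape/rate `k = (mean/sd)^2, z = mean/sd^2` — the only choice consistent
with reporting a coefficient as mean ± sd. For a coefficient whose sd is a
large fraction of its mean (e.g. a gamma-curve linear term known only to
~70%), the matched Gamma is strongly skewed; that is accepted as-is.

## Posterior evaluation

`P(D_x) = ∫ L(D_x|theta) p(theta) dtheta` is computed per dose-grid point
by adaptive vector quadrature (`scipy.integrate.quad_vec`) on
`(1e-9, 1-1e-9)`, split at the prior's breakpoints. The saturated Poisson
log likelihood (`u ln u - u - ln u!`) is subtracted before exponentiation,
so the `u = 85` likelihood, whose raw power term overflows double
precision, stays in range; the constant cancels in normalization.

Dose grid: 2000 points from 0 to an automatic upper bound (4x the
classical solve at the prior's central ratio), extended by factors of 1.6
until the right-tail density falls below 1e-6 of the peak and the mode is
interior. The density is normalized by the trapezoid rule; the grid-argmax
mode is refined by a three-point parabola on the log density (the residual
grid-discretization error is far below the 0.5% level at which the
degenerate-prior limit is verified).

Point estimate: the posterior **mode** (the posterior mean and a central
95% credible interval are also reported; for the sharp informative priors
of interest mode and mean differ by well under the quoted uncertainties,
but for flat priors the marginals are strongly skewed and the distinction
matters — the diagnostics carry both).

Uncertainty: the Cramér–Rao bound `1/sqrt(|d² ln P/dD²|)` from a centered
second difference at the grid mode. It is a *lower* bound and is labelled
as such; degenerate shapes (mode on the boundary, non-concave log density)
raise rather than return a number, and the pair-estimate surface reports
NaN in that case. On the reactor-sample fixtures this bound matches the
width implied by the credible interval to within a few tens of percent.

Defining property (and the module's main correctness anchor): as the
fraction prior collapses to a point at `theta0`, the posterior mode
converges to the classical solution at `rho = 1/theta0 - 1`. A corollary
worth stating: for a ratio prior centred at `rho0`, the *neutron* marginal
mode always sits at or above the fixed-ratio solution (the likelihood
geometry weights larger-`D_n` configurations), approaching it from above
as the prior sharpens; the gamma marginal approaches its fixed-ratio value
from below.

## Full-Bayes integration

The 4-D integral (theta plus up to three Gamma axes; a background with an
sd adds a fifth) uses a tensor product: 24-node Gauss–Legendre per Gamma
axis on `[max(mean-8sd, 0+), mean+8sd]` with weights multiplied by the
Gamma density and renormalized (compensating truncation), and theta nodes
allocated per breakpoint segment. An sd of zero collapses its axis to a
point, which reproduces the simplified posterior to within quadrature
tolerance — tested pointwise. The Monte Carlo integrator (mandatory
explicit seed) samples the same distributions and agrees with the tensor
rule on the mode to ~1% at 1e5 draws; it exists as a cross-check and as
the escape hatch for high-dimensional multi-field problems.

## Multi-field engine

For R types the yield is `Y0 + sum_i sum_j lambda_ij D_i^j` (degrees <= 3).
The free fractions are `theta_1..theta_{R-1}` with the last derived, and
the posterior of component i integrates over the simplex
`sum theta < 1` with independent priors per free fraction. The published
reparameterized bracket nests the fraction substitution inside the
polynomial; the implementation instead reconstructs all R doses from
`(D_i, theta)` — `D_total = D_i/theta_i`, `D_j = theta_j D_total` — and
evaluates the plain polynomial, which is algebraically identical and
avoids compounding the nesting. R = 2 with fixed coefficients reduces
exactly to the simplified two-field estimator (single free fraction,
same adaptive quadrature); R <= 4 uses the deterministic tensor rule,
beyond that the seeded Monte Carlo integrator is required.

## Calibration fitting

Poisson maximum likelihood with non-negativity box bounds (L-BFGS-B),
started from a clipped least-squares fit of the raw frequencies; sds from
the inverse observed information (central-difference Hessian). Linear fits
fill the high-LET slot (`alpha`), linear-quadratic fits the low-LET slots
(`beta`, `gamma`). `compare_forms` is a plain AIC comparison with
`|dAIC| < 2` reported as indeterminate — deliberately *not* a Bayesian
model-selection procedure, and labelled accordingly. The packaged fixture
curves ship as constants (their underlying scoring data are not public);
fitting is validated purely by simulation recovery, where the fitted
parameters are consistent with the generating ones and bias shrinks as
cells-per-point grow.

## Simulator

The generator draws `u ~ Poisson(w * Y(doses))` — exactly the assumption
the estimators invert. Simulated tests therefore demonstrate internal
consistency (correct inversion, calibrated intervals under the model), not
robustness to what real scoring data add: overdispersion from partial-body
exposure or dose heterogeneity, misclassified aberrations, inter-scorer
variability. Every draw requires an explicit seed; identical seeds give
byte-identical calibration tables.

Default study conditions mirror the worked examples: reactor-field truth
(D_n, D_gamma) = (0.069, 0.796) Gy at 500 cells with the reactor-lab
curve, and 5000 cells per point on an 8-dose design (0–4 Gy) for
calibration recovery.

## Known limitations

* Poisson-only counting statistics; no u-test/overdispersion screening.
* The Cramér–Rao sigma understates uncertainty for skewed posteriors; use
  the credible intervals when the prior is weak.
* The simplified method ignores coefficient uncertainty *in the posterior*
  by design; the finite-increments budget of the classical solvers is the
  place where those sds enter.
* Multi-field calibration (fitting lambda from multi-field exposures) is
  out of scope; identifiability is not addressed.
* Robust Bayesian curve fitting is not implemented; the CLI reserves
  `fit --method robust-bayes` with a clear message.
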