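# biodose

Mixed-field (neutron + gamma) cytogenetic biodosimetry: estimating the
separate absorbed-dose components of a mixed radiation field from
dicentric-chromosome counts.

## The problem

After an accidental exposure in a mixed neutron + gamma field (a research
reactor, a criticality accident), the dicentric assay counts `u` dicentric
chromosomes in `w` scored lymphocytes. Because neutrons and gamma rays have
very different biological effectiveness, the *components* `D_n` and
`D_gamma` of the absorbed dose matter, not just their sum. With in-vitro
calibration curves

    Y_gamma(D) = Y0 + beta*D + gamma*D^2        (low LET, linear-quadratic)
    Y_n(D)     = Y0 + alpha*D                   (high LET, linear)

and additive dicentric production, the observed frequency `y_f = u/w`
satisfies

    y_f = Y0 + alpha*D_n + beta*D_gamma + gamma*D_gamma^2 .

One equation, two unknowns: the missing ingredient is the field composition,
expressed as the dose ratio `rho = D_n/D_gamma` or, more conveniently, the
gamma dose fraction `theta = D_gamma/(D_gamma + D_n) = 1/(rho + 1)`.

## The methods

* **Classical** (`analytical`, `iterative`) — `rho` known from physical
  dosimetry. The yield equation becomes a quadratic in `D_gamma`, solved in
  closed form or by the classical subtraction iteration. Uncertainties by
  independent finite increments (Poisson `sqrt(u)`, coefficient sds, `sd_rho`).
* **Simplified Bayesian** (`bayes`) — `rho` uncertain; curve coefficients
  fixed at their fitted values. The posterior of each dose component is a
  1-D marginalization of the Poisson likelihood over a prior on `theta`:

      P(D_x) = ∫₀¹ L(D_x | theta) p(theta) dtheta ,   x ∈ {gamma, n}

  with a catalogue of priors: Gaussian in `theta`, scaled Gaussian (Gaussian
  in `rho` expressed in `theta`), Beta, simplified Beta `theta(1-theta)`,
  sigmoidal threshold ramps, and constant. The point estimate is the
  posterior mode; the quoted sigma is the Cramér–Rao lower bound from the
  log-posterior curvature at the mode.
* **Full Bayesian** (`bayes_full`) — additionally marginalizes
  `alpha, beta, gamma` over moment-matched Gamma priors (4-D integral,
  deterministic tensor quadrature or seeded Monte Carlo).
* **Multi-field** (`biodose.multi_field`) — the R-type generalization with
  per-type polynomial yields and R−1 fraction priors on the simplex.

Poisson maximum-likelihood calibration fitting, a forward simulator, and a
bias/RMSE/coverage recovery study round out the toolbox.

## Worked example

A reactor-field sample with 35 dicentrics in 500 cells; the gamma fraction
is known from kerma measurements to be 0.92 ± 0.02
(`rho = 1/0.92 − 1 ≈ 0.087`):

```python
import biodose as bd

model = bd.MixedFieldModel.from_counts(35, 500, bd.load_curve("clor_bm"))
res = model.fit(method="bayes", prior=bd.GaussianPrior(0.92, 0.02))
print(res.summary())
```

```
Mixed-field dose estimate
==============================================
method                bayes_simplified
D_gamma [Gy]          0.7981 +/- 0.1036
D_n     [Gy]          0.0714 +/- 0.0157
D_total [Gy]          0.8695
prior                 GaussianPrior(theta_hat=0.92, sigma_theta=0.02)
uncertainty           cramer_rao_lower_bound
gamma 95% CrI [Gy]    (0.6095, 1.0130)
neutron 95% CrI [Gy]  (0.0422, 0.1059)
==============================================
```

The posterior mode puts the gamma dose at 0.798 Gy and the neutron dose at
0.071 Gy — close to the physically measured 0.782/0.068 Gy, and matching
the classical solver at the measured ratio (`model.fit(method="iterative",
rho=0.087)` gives 0.798/0.069 Gy). With an uninformative constant prior the
gamma estimate collapses to ~0.22 Gy: the ratio information, not the count,
is what separates the components.

The same interface runs from the shell:

```sh
biodose estimate --method bayes-simplified --u 35 --w 500 --curve clor_bm \
    --prior gaussian:theta_hat=0.92,sigma_theta=0.02 --dump-posterior post.csv
biodose fit --data calib.csv --form lq --out curve.json
biodose simulate --dn 0.068 --dgamma 0.782 --curve clor_bm --cells 500 --seed 42
```

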