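# lqreg

Sparse linear regression for heavy-tailed data, built on the
**Lq-likelihood** and the **q-normal** error family.

## The problem

Regularized least squares (LASSO, SCAD, MCP) is the workhorse for variable
selection in the normal linear model

y_a = θ₀ + Σᵢ x_ia θᵢ + ε_a,   a = 1,…,n,

but real responses — survival times, expression counts, exposure
measurements — are often heavy-tailed. A natural heavy-tailed error family
is the *q-normal* distribution

f_q(y | ξ, σ) = (1 / σZ_q) · exp_q( −((y−ξ)/σ)² / (3−q) ),

built from the deformed exponential exp_q(u) = {1+(1−q)u}^{1/(1−q)}. For
1 ≤ q < 3 it is supported on all of ℝ: q = 1 is the Gaussian, q = 2 the
Cauchy, and in general it is a scaled Student-t with ν = (3−q)/(q−1)
degrees of freedom. Pairing this error law with the **Lq-likelihood**

L_q(θ | y) = Σ_a log_q f(y_a | θ),   log_q(u) = (u^{1−q} − 1)/(1−q),

gives an estimation theory in which the deformation of the likelihood and
the deformation of the error family cancel: for the q-normal linear model
(σ = 1 known),

L_q(θ | y) = −(Z_q^{q−1}/(3−q)) · ‖y − Xθ‖² + const,

an affine decreasing function of the residual sum of squares. Two
consequences drive this package:

* the **maximum Lq-likelihood estimator (MLqE) is ordinary least squares**,
  for every q;
* **Lq-likelihood-based regularization**, min −(1/n)L_q(θ|y) + ρ_λ(θ), is
  the ordinary penalized least squares problem
  min (1/2n)‖y−Xθ‖² + ρ_{λ′}(θ) after the mapping
  λ′ = λ(3−q) / (2Z_q^{q−1}).

So heavy-tailed (q-normal) sparse regression can be solved with the
standard machinery — what changes is how you *select* a model. `lqreg`
provides the whole pipeline: the q-normal toolkit, a coordinate-descent
solver for LASSO / SCAD / MCP paths, information criteria based on both the
ordinary log-likelihood (AIC/BIC) and the Lq-likelihood (Lq-AIC/Lq-BIC) —
each evaluated at the raw path estimate ("2" variants) or at a submodel MLE
refit ("1" variants, t-regression by IRLS) — plus K-fold cross-validation
and a Monte-Carlo harness for model-selection and generalization studies.

## Worked example

Data with t₃ errors (q = 3/2), n = 100, d = 10, two true slopes of 10:

```python
import numpy as np
from lqreg import (QSpec, Dataset, ExperimentConfig, fit_path, evaluate_path,
                   select, run_experiment, gen_design, gen_response, gen_true_theta)

q = 3/2                     # t-distribution errors with nu = 3
spec = QSpec(q)
theta_true = gen_true_theta(d=10, rnz=0.2, theta_star=10.0)
design = gen_design(n=100, d=10, seed=1)
y = gen_response(design, theta_true, spec, seed=2)
data = Dataset(np.column_stack([np.ones(100), design]), y)

path = fit_path(data, "mcp")                      # warm-started 100-lambda path
table = evaluate_path(path, data, spec, criteria=("BIC2",))
k, support = select(table, "BIC2")
print("chosen lambda:", round(float(path.lambdas[k]), 4))
print("selected support:", support.sorted())
print("true support:   ", theta_true.support().sorted())
print("slope estimates:", np.round(path.coefs[k].slopes[:3], 2))
```

prints

```
chosen lambda: 0.2925
selected support: [1, 2]
true support:    [1, 2]
slope estimates: [ 6.51 11.21  0.  ]
```

MCP with BIC2 recovers the true two-variable model exactly; the slope
estimates sit near the truth (10) despite the infinite-kurtosis noise.
A small Monte-Carlo comparison of the three penalties at the same setting:

```python
config = ExperimentConfig(q=q, n=100, d=10, rnz=0.2, theta_star=10.0,
                          m=20, seed=0, criteria=("BIC2",))
summary, _ = run_experiment(config)
print(summary[["penalty", "criterion", "recovered", "m", "gen_mse_median"]].to_string(index=False))
```

```
penalty criterion  recovered  m  gen_mse_median
  lasso      BIC2          9 20        2.780763
    mcp      BIC2         17 20        2.587603
   scad      BIC2         17 20        2.587603
```

`recovered` counts trials whose selected support equals the true support
exactly; `gen_mse_median` is the median (over trials) of the mean squared
prediction error on a fresh test set. For t₃ noise the error variance is
ν/(ν−2) = 3, and the per-trial MSE is a mean of heavy-tailed squares, so
its median across trials sits somewhat below that value while its mean is
dragged above it — both are reported by `run_experiment`. The nonconvex
penalties dominate the LASSO for exact support recovery, and the advantage
grows with m (88 vs 43 out of 100 at m = 100).

## Command line

```
lqreg fit      --x X.csv --y y.csv --penalty mcp --lam 0.05 [--q 1.5]
lqreg path     --x X.csv --y y.csv --penalty scad --out path.csv
lqreg select   --x X.csv --y y.csv --criterion BIC2 --json
lqreg simulate --config exp.yaml --out results/
```

`fit`/`select` standardize the design internally (centered, unit-norm
columns) and report coefficients on the original scale; `path` emits a tidy
(lambda, index, value) CSV; `simulate` runs an `ExperimentConfig` given as
YAML and writes `summary.csv`, `trials.csv` and run metadata.

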