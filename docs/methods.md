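# Methods

## Model

The package treats the linear model y = Xθ + ε with i.i.d. q-normal errors
of known unit dispersion. The design matrix carries a leading all-ones
intercept column; every other column is centered and scaled to unit
Euclidean norm (‖xᵢ‖ = 1), and the response is left unscaled. All internal
computations use this scale; `StandardizeTransform.destandardize` maps
coefficients back to the original units, and the algebraic identity that
fitted values are preserved under the round trip is tested.

The q-normal family, 1 ≤ q < 3, is parameterized by the deformation q with
derived constants ν = (3−q)/(q−1) (Student-t degrees of freedom; ∞ at
q = 1) and Z_q = √ν·B(ν/2, ½) (normalizer; √(2π) at q = 1). Values q < 1
(compact support) and q ≥ 3 (non-normalizable) are rejected at
construction. Sampling uses the exact location–scale Student-t
representation Y = ξ + σT rather than a generalized Box–Müller transform:
it is exact, and testable against closed-form t and Cauchy CDFs. Within
|q−1| < 1e−10 the Gaussian branch is used for log_q/exp_q and the density,
to avoid catastrophic cancellation in the power-function forms.

## Likelihoods and the estimator

`lq_likelihood` sums q-logarithms of the density directly. For this model
the sum is affine decreasing in the residual sum of squares with slope
Z_q^{q−1}/(3−q); the constant term of the expansion is n·log_q(1/Z_q) =
−n·Z_q^{q−1}·log_q(Z_q). Direct summation is the implementation; the
affine slope is used as an independent oracle in tests. Because the
Lq-likelihood is monotone in ‖y−Xθ‖², its maximizer (the MLqE) is the
ordinary least-squares fit for every q — `mlqe` computes exactly that, with
an explicit rank check and no pseudo-inverse fallback (a rank-deficient
design is an error, not a silent minimum-norm answer).

Submodel MLE refits under q > 1 are Student-t regressions with known
scale, solved by iteratively reweighted least squares with weights
(ν+1)/(ν+r²), initialized at the OLS refit, tolerance 1e−8 on the
coefficient change, at most 500 iterations. For q ≥ 2 (Cauchy-like, the
likelihood can be multimodal) five seeded restarts perturb the OLS start
and the best local maximum is kept. A refit is declared *unavailable*
unless IRLS converged and the Hessian at the solution is negative definite;
unavailable refits propagate as missing "IC1" criterion values rather than
errors.

## Penalties and the solver

LASSO, SCAD (a > 2, default 3.7) and MCP (γ > 0, default 3) are separable
over slopes; the intercept is never penalized. The SCAD middle branch is
taken as −(t² − 2aλt + λ²)/(2(a−1)), the only reading continuous at t = λ
and t = aλ; continuity at both breakpoints is unit-tested.

The solver minimizes (1/2n)‖y−Xθ‖² + ρ_λ(θ) by cyclic coordinate descent.
With unit-norm columns the coordinate subproblem is
argmin_t ½(z−t)² + w·ρ_λ(t) with penalty weight w = n/‖xⱼ‖² (= n). Two
consequences of this convention matter and are deliberate:

* For w above the concavity limits (γ for MCP, a−1 for SCAD) the scalar
  subproblem is nonconvex. The prox is therefore computed by exact
  enumeration of the per-branch stationary points and breakpoints of the
  piecewise-quadratic objective — exact for every weight — with ties broken
  toward smaller |t| (the sparser solution), deterministically. In this
  regime both penalties act close to hard thresholding (the flat region
  begins at a few multiples of λ), which is why they behave like best-subset
  selection in the experiments.
* The all-zero λ differs across families: λ_max = max_j |x_jᵀ(y−ȳ)|/n for
  the LASSO, but larger by ≈ √(n/γ) (MCP) and ≈ √(n/(a+1)) (SCAD) factors
  for the nonconvex penalties, where the zero/nonzero comparison is between
  ½z² and the saturated penalty. `lambda_grid` computes the family-correct
  λ_max (closed form, then verified against the prox) and lays a
  log-spaced grid of 100 values down to min_ratio·λ_max, with min_ratio
  0.001 (n > d) or 0.05 (n ≤ d). Paths are warm-started from the previous
  λ. Without the family-correct grid the nonconvex paths never visit their
  sparse regime and model selection over the path is meaningless.

Convergence is declared when the largest coefficient change in a sweep
falls below 1e−7 (at most 10⁴ sweeps). Exact scalar minimization makes the
objective monotone per sweep, which the suite checks; it also implies that
a sweep with an ulp-level objective decrease but moving coefficients is a
cycle between exactly tied nonconvex minima — after three such sweeps the
solver stops, flagging non-convergence unless the residual movement is
negligible. For the LASSO the result is the global minimum (verified
against a brute-force grid and KKT conditions); for SCAD/MCP only
stationarity is claimed.

A `loss_weight` c generalizes the objective to c·(1/2n)‖y−Xθ‖² + ρ_λ(θ),
which with c = 2Z_q^{q−1}/(3−q) is exactly the Lq-regularization objective
−(1/n)L_q + ρ_λ (`fit_lq`). For the LASSO this coincides with the plain
problem at λ′ = λ(3−q)/(2Z_q^{q−1}) (`lambda_for_least_squares`); for MCP
the same holds with γ′ = cγ, because (1/c)·MCP_{λ,γ} = MCP_{λ/c, cγ}
exactly. For SCAD, (1/c)·SCAD_{λ,a} is not itself a SCAD member (its
breakpoints do not move), so the λ-only mapping is exact for LASSO,
exact-with-γ-map for MCP, and for SCAD the equivalence is at the level of
the rescaled objective, which `fit_lq` solves directly.

## Model selection

Eight deviance-form criteria: AIC/BIC on the ordinary (Student-t)
log-likelihood and Lq-AIC/Lq-BIC on the Lq-likelihood, each at the raw path
estimate ("2") or at the submodel MLE refit ("1"). The parameter count d′
is the intercept plus the nonzero slopes; σ is known and not counted. All
criteria are minimized; ties go to the larger λ (sparser model). Refits
are cached per distinct support along the path. At q = 1 the Lq criteria
coincide with the ordinary ones identically.

Cross-validation uses K = 10 contiguous folds of a seeded permutation (K
is a declared default; nothing in the underlying design fixes it) and
squared prediction error even under heavy tails — matching the
generalization metric — with the caveat that for q ≥ 2 the fold means have
infinite variance and CV can be erratic; replicate calibration showed
single-run chosen-λ CV errors spreading roughly ±40% around the noise
variance even at q = 1, so the suite asserts on a replicate average.

## Synthetic study

The generator draws a fresh standard-normal n×d design per trial,
standardizes it, places the d·rnz nonzero coefficients (value θ*) in the
leading coordinates (exchangeability of the Gaussian design makes the
positions irrelevant, which a permutation check confirms), and adds
q-normal(0, 1) noise. The factorial design is d ∈ {10,100} ×
rnz ∈ {0.2,…,0.8} × θ* ∈ {1,…,1000}, 32 numbered cases, with q drawn from
{1, 13/11, 3/2, 5/3, 2, 2.01, 2.1, 2.5} and n ∈ {100, 1000} in replication
mode. Per-trial seeds derive from the master seed via
`SeedSequence(seed, spawn_key=(trial, stream))`, so runs are bit-for-bit
reproducible and any single trial can be re-run in isolation.

Generalization error is the per-observation mean squared prediction error
on one fresh (X′, y′) of size n per trial; the absolute-error analogue and
the median across trials are also reported, because for q ≥ 2 the squared
error has infinite mean and the trial-mean is unstable by construction —
the median is the robust summary there. The default replication scale is
m = 100 trials per cell (configurable to 1000); the packaged tests use
m = 100 at n ∈ {100, 1000}, d = 10, which keeps the full suite at a few
minutes on one core.

Because the design columns are standardized to unit norm, a coefficient θ*
contributes signal of order θ*/√n per observation; θ* = 10 at n = 100 is
therefore a moderate-signal regime, not an overwhelming one. What the
passing tests show is confined to this synthetic world: exchangeable
Gaussian designs, exactly sparse truths with equal-magnitude coefficients,
known unit dispersion, and errors that are exactly q-normal. Correlated
designs, unequal coefficients, unknown or heteroskedastic scale, and
misspecified error families are all outside what the study exercises.

## Known limitations

* σ is fixed at 1 throughout; no dispersion estimation.
* SCAD/MCP fits are stationary points, not certified global minima.
* The exact LARS path is not implemented; paths are λ-grids with warm
  starts.
* Multivariate q-normals and q outside [1, 3) are out of scope.
* Under q ≥ 2 the generalization summaries (and CV) inherit the
  infinite-variance pathology of squared error; interpret means with care
  and prefer the reported medians.
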