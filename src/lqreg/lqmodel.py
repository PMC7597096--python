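"""The q-normal linear model: likelihoods, the MLqE, and submodel MLE refits.

Model: ``y_a = theta_0 + sum_i x_ia theta_i + eps_a`` with i.i.d. q-normal
errors of known dispersion (sigma = 1).  Two fit functionals live here:

* the ordinary log-likelihood ``sum_a log f_q(y_a | x_a theta)`` — for q>1
  this is a Student-t error likelihood;
* the Lq-likelihood ``sum_a log_q f_q(y_a | x_a theta)``, which for the
  q-normal linear model is an affine *decreasing* function of the residual
  sum of squares with slope ``Zq^(q-1)/(3-q)``.  Its maximizer, the MLqE,
  therefore coincides with ordinary least squares for every q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qcore import QSpec, log_q, q_normal_pdf

__all__ = [
    "Dataset",
    "Coefficients",
    "Support",
    "lq_likelihood",
    "log_likelihood",
    "mlqe",
    "submodel_mle",
]

_STD_TOL = 1e-8


@dataclass(frozen=True)
class Dataset:
    """Design matrix with leading intercept column and response vector.

    ``X`` has shape ``(n, d+1)``; column 0 is all ones.  Under the model's
    standing convention each non-intercept column is centered and scaled to
    unit Euclidean norm; construction checks this unless
    ``require_standardized=False`` (useful for hand-built toy fixtures).
    """

    X: np.ndarray
    y: np.ndarray
    require_standardized: bool = True

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent sample sizes")
        if X.shape[0] < 2:
            raise ValueError("need n >= 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite (no missing values)")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("column 0 of X must be the all-ones intercept")
        if self.require_standardized and X.shape[1] > 1:
            cols = X[:, 1:]
            if not (
                np.allclose(cols.sum(axis=0), 0.0, atol=1e-6)
                and np.allclose(np.linalg.norm(cols, axis=0), 1.0, atol=1e-6)
            ):
                raise ValueError(
                    "non-intercept columns must be centered with unit norm; "
                    "use solver.standardize() or pass require_standardized=False"
                )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1] - 1


@dataclass(frozen=True)
class Coefficients:
    """Regression coefficients: intercept plus d slopes."""

    intercept: float
    slopes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "intercept", float(self.intercept))
        object.__setattr__(self, "slopes", np.asarray(self.slopes, dtype=float).ravel())

    def as_array(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.slopes])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "Coefficients":
        theta = np.asarray(theta, dtype=float).ravel()
        return cls(theta[0], theta[1:])

    def support(self, tol: float = 0.0) -> "Support":
        nz = np.flatnonzero(np.abs(self.slopes) > tol) + 1
        return Support(frozenset(int(i) for i in nz))


@dataclass(frozen=True)
class Support:
    """Set of slope indices (1-based, intercept always implicitly included)."""

    indices: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", frozenset(int(i) for i in self.indices))

    def validate(self, d: int) -> None:
        if self.indices and not self.indices <= set(range(1, d + 1)):
            raise ValueError(f"support indices must lie in 1..{d}")

    def __len__(self) -> int:
        return len(self.indices)

    def sorted(self) -> list[int]:
        return sorted(self.indices)


def _residuals(theta: Coefficients, data: Dataset) -> np.ndarray:
    return data.y - data.X @ theta.as_array()


def lq_likelihood(theta: Coefficients, data: Dataset, spec: QSpec) -> float:
    """Lq-likelihood ``sum_a log_q f_q(y_a | x_a theta, sigma=1)``.

    Computed by direct summation of q-logarithms of the density; equal to
    ``-(Zq^(q-1)/(3-q)) * ||y - X theta||^2 + n*log_q(1/Zq)``, i.e. affine
    decreasing in the residual sum of squares.
    """
    r = _residuals(theta, data)
    dens = q_normal_pdf(r, spec=spec)
    return float(np.sum(log_q(dens, spec.q)))


def log_likelihood(theta: Coefficients, data: Dataset, spec: QSpec) -> float:
    """Ordinary log-likelihood under q-normal errors (Student-t for q>1)."""
    r = _residuals(theta, data)
    if spec.is_gaussian:
        n = data.n
        return float(-0.5 * np.dot(r, r) - n * np.log(spec.Zq))
    nu = spec.nu
    return float(
        -((nu + 1.0) / 2.0) * np.sum(np.log1p(r * r / nu)) - data.n * np.log(spec.Zq)
    )


def mlqe(data: Dataset, spec: QSpec | None = None) -> Coefficients:
    """Maximum Lq-likelihood estimator — the ordinary least-squares fit.

    Independent of q, because the Lq-likelihood of the q-normal linear model
    is a decreasing affine function of the residual sum of squares.  Raises
    on rank-deficient designs (no pseudo-inverse fallback).
    """
    X = data.X
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix is rank-deficient (rank {rank} < {X.shape[1]} columns)"
        )
    theta, *_ = np.linalg.lstsq(X, data.y, rcond=None)
    return Coefficients.from_array(theta)


def _irls_t_mle(
    Xs: np.ndarray, y: np.ndarray, nu: float, theta0: np.ndarray,
    tol: float = 1e-8, max_iter: int = 500,
) -> tuple[np.ndarray, bool]:
    """IRLS for the t-location regression MLE with known sigma=1.

    Weights ``(nu+1)/(nu + r^2)`` reproduce the score equations of the
    Student-t likelihood; this is the classical EM scheme for t regression.
    """
    theta = theta0.copy()
    for _ in range(max_iter):
        r = y - Xs @ theta
        w = (nu + 1.0) / (nu + r * r)
        Xw = Xs * w[:, None]
        try:
            theta_new = np.linalg.solve(Xs.T @ Xw, Xw.T @ y)
        except np.linalg.LinAlgError:
            return theta, False
        if np.max(np.abs(theta_new - theta)) < tol:
            return theta_new, True
        theta = theta_new
    return theta, False


def _t_loglik(Xs: np.ndarray, y: np.ndarray, nu: float, theta: np.ndarray) -> float:
    r = y - Xs @ theta
    return float(-((nu + 1.0) / 2.0) * np.sum(np.log1p(r * r / nu)))


def _hessian_negdef(Xs: np.ndarray, y: np.ndarray, nu: float, theta: np.ndarray) -> bool:
    # Hessian of the t log-likelihood: -X^T diag(h) X with
    # h = (nu+1)(nu - r^2)/(nu + r^2)^2; negative definite iff X^T diag(h) X > 0
    r = y - Xs @ theta
    h = (nu + 1.0) * (nu - r * r) / (nu + r * r) ** 2
    H = Xs.T @ (Xs * h[:, None])
    try:
        eig = np.linalg.eigvalsh(H)
    except np.linalg.LinAlgError:
        return False
    return bool(eig.min() > 0)


def submodel_mle(
    data: Dataset,
    support: Support,
    spec: QSpec,
    *,
    seed: int = 0,
    n_restarts_cauchy: int = 5,
) -> Coefficients | None:
    """MLE of the submodel with slopes outside ``support`` pinned at zero.

    q=1 reduces to OLS on the selected columns.  For q>1 the Student-t MLE
    is computed by IRLS initialized at the OLS refit; near q=2 the Cauchy
    likelihood can be multimodal, so a few seeded restarts around the OLS
    fit are tried and the best local maximum kept.  Returns ``None``
    ("unavailable") when IRLS fails to converge or the Hessian at the
    solution is not negative definite.
    """
    support.validate(data.d)
    idx = [0] + support.sorted()
    if len(idx) > data.n:
        raise ValueError("support larger than sample size")
    Xs = data.X[:, idx]
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        return None
    theta_ols, *_ = np.linalg.lstsq(Xs, data.y, rcond=None)

    if spec.is_gaussian:
        full = np.zeros(data.d + 1)
        full[idx] = theta_ols
        return Coefficients.from_array(full)

    nu = spec.nu
    starts = [theta_ols]
    if spec.q >= 2.0:
        rng = np.random.default_rng(seed)
        scale = 0.1 * (1.0 + np.abs(theta_ols))
        starts += [theta_ols + scale * rng.standard_normal(theta_ols.shape)
                   for _ in range(n_restarts_cauchy)]

    best, best_ll = None, -np.inf
    for start in starts:
        theta, ok = _irls_t_mle(Xs, data.y, nu, start)
        if not ok:
            continue
        ll = _t_loglik(Xs, data.y, nu, theta)
        if ll > best_ll:
            best, best_ll = theta, ll
    if best is None or not _hessian_negdef(Xs, data.y, nu, best):
        return None
    full = np.zeros(data.d + 1)
    full[idx] = best
    return Coefficients.from_array(full)
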