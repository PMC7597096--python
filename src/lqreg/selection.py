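"""Model selection along a regularization path.

Eight information criteria are supported, the deviance-form AIC/BIC and
their Lq-likelihood analogues,

    AIC  = -2 log p(y|theta) + 2 d',     BIC  = -2 log p(y|theta) + d' log n,
    LqAIC = -2 Lq(theta|y)   + 2 d',     LqBIC = -2 Lq(theta|y)   + d' log n,

each in two flavors: the "1" variants evaluate the criterion at the MLE
refit of the selected submodel (available only when that MLE exists), the
"2" variants at the raw path estimate itself.  d' counts the intercept plus
the nonzero slopes (sigma is known).  K-fold cross-validation on squared
prediction error is provided as a further selector; note that under very
heavy tails (q >= 2) the squared-error CV mean is itself heavy-tailed and
can be erratic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lqmodel import Coefficients, Dataset, Support, log_likelihood, lq_likelihood, submodel_mle
from .qcore import QSpec
from .solver import PathFit, fit_path

__all__ = [
    "CRITERIA",
    "CriterionValue",
    "aic",
    "bic",
    "lq_aic",
    "lq_bic",
    "evaluate_path",
    "select",
    "CVResult",
    "cross_validate",
]

CRITERIA = ("AIC1", "AIC2", "BIC1", "BIC2", "LqAIC1", "LqAIC2", "LqBIC1", "LqBIC2")


def aic(loglik: float, d_prime: int) -> float:
    return -2.0 * loglik + 2.0 * d_prime


def bic(loglik: float, d_prime: int, n: int) -> float:
    return -2.0 * loglik + d_prime * math.log(n)


def lq_aic(lqlik: float, d_prime: int) -> float:
    return -2.0 * lqlik + 2.0 * d_prime


def lq_bic(lqlik: float, d_prime: int, n: int) -> float:
    return -2.0 * lqlik + d_prime * math.log(n)


@dataclass(frozen=True)
class CriterionValue:
    criterion: str
    k: int
    value: float
    d_prime: int
    available: bool
    support: tuple


def evaluate_path(
    path: PathFit,
    data: Dataset,
    spec: QSpec,
    criteria=CRITERIA,
    *,
    refit_seed: int = 0,
) -> pd.DataFrame:
    """Evaluate information criteria at every path point.

    Returns a tidy frame with one row per (path index, criterion).  MLE
    refits for the "1" variants are cached per distinct support, so
    duplicate supports along the path cost one refit.  Unavailable refits
    yield ``available=False`` rows with NaN values.
    """
    criteria = tuple(criteria)
    unknown = set(criteria) - set(CRITERIA)
    if unknown:
        raise ValueError(f"unknown criteria: {sorted(unknown)}")
    need_refit = any(c.endswith("1") for c in criteria)
    need_lq = any(c.startswith("Lq") for c in criteria)
    need_log = any(not c.startswith("Lq") for c in criteria)

    refit_cache: dict[frozenset, Coefficients | None] = {}
    rows: list[CriterionValue] = []
    logn = math.log(data.n)
    for k, coef in enumerate(path.coefs):
        supp = coef.support()
        d_prime = len(supp) + 1
        supp_t = tuple(supp.sorted())
        ll2 = log_likelihood(coef, data, spec) if need_log else np.nan
        lq2 = lq_likelihood(coef, data, spec) if need_lq else np.nan
        if need_refit:
            if supp.indices not in refit_cache:
                refit_cache[supp.indices] = submodel_mle(data, supp, spec, seed=refit_seed)
            refit = refit_cache[supp.indices]
            ll1 = log_likelihood(refit, data, spec) if refit is not None and need_log else np.nan
            lq1 = lq_likelihood(refit, data, spec) if refit is not None and need_lq else np.nan
            refit_ok = refit is not None
        else:
            ll1 = lq1 = np.nan
            refit_ok = False
        fits = {"AIC1": ll1, "BIC1": ll1, "LqAIC1": lq1, "LqBIC1": lq1,
                "AIC2": ll2, "BIC2": ll2, "LqAIC2": lq2, "LqBIC2": lq2}
        for crit in criteria:
            penalty_term = 2.0 * d_prime if "AIC" in crit else d_prime * logn
            val = -2.0 * fits[crit] + penalty_term
            avail = refit_ok if crit.endswith("1") else True
            rows.append(CriterionValue(crit, k, float(val), d_prime, bool(avail), supp_t))
    return pd.DataFrame(rows)


def select(values: pd.DataFrame, criterion: str) -> tuple[int, Support]:
    """Pick the path index minimizing one criterion.

    Ties go to the smaller path index, i.e. the larger lambda and hence the
    sparser candidate.  Raises if no entry of the criterion is available.
    """
    sub = values[(values["criterion"] == criterion) & values["available"]]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"criterion {criterion!r} has no available entries")
    sub = sub.sort_values("k", kind="stable")
    best = sub.loc[sub["value"].idxmin()]  # idxmin returns first minimum in order
    return int(best["k"]), Support(frozenset(best["support"]))


@dataclass
class CVResult:
    lambdas: np.ndarray
    cv_errors: np.ndarray
    chosen_index: int
    chosen_lambda: float
    fold_sizes: list


def cross_validate(
    data: Dataset,
    family: str = "lasso",
    *,
    a: float = 3.7,
    gamma: float = 3.0,
    K: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    nlambda: int = 100,
    min_ratio: float | None = None,
    loss_weight: float = 1.0,
) -> CVResult:
    """K-fold cross-validation of a penalized path on squared error.

    Folds are contiguous blocks of a seeded permutation of the rows.  The
    lambda grid is computed once on the full data and reused per fold.
    Folds whose training design is degenerate (a zero-norm column) are
    skipped with a warning.
    """
    from .solver import lambda_grid

    if K < 2:
        raise ValueError("K must be >= 2")
    if data.n < K:
        raise ValueError("need n >= K")
    if lambdas is None:
        lambdas = lambda_grid(
            data, nlambda=nlambda, min_ratio=min_ratio,
            family=family, a=a, gamma=gamma, loss_weight=loss_weight,
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n)
    folds = np.array_split(perm, K)

    errors = np.zeros((K, len(lambdas)))
    used = np.zeros(K, dtype=bool)
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        Xtr, ytr = data.X[train_idx], data.y[train_idx]
        if np.any(np.einsum("ij,ij->j", Xtr, Xtr) <= 1e-14):
            warnings.warn(f"fold {f}: degenerate training design, skipped", RuntimeWarning)
            continue
        train = Dataset(Xtr, ytr, require_standardized=False)
        pathf = fit_path(
            train, family, a=a, gamma=gamma, lambdas=lambdas, loss_weight=loss_weight
        )
        Xte, yte = data.X[test_idx], data.y[test_idx]
        preds = Xte @ pathf.coef_matrix().T
        errors[f] = np.mean((preds - yte[:, None]) ** 2, axis=0)
        used[f] = True
    if not used.any():
        raise ValueError("all folds degenerate")
    cv = errors[used].mean(axis=0)
    k = int(np.argmin(cv))
    return CVResult(np.asarray(lambdas), cv, k, float(lambdas[k]), [len(f) for f in folds])
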