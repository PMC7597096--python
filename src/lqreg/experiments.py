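"""Synthetic-data generator and the Monte-Carlo simulation harness.

The study design: a fresh n x d standard-normal design per trial,
standardized to centered unit-norm columns; a sparse true coefficient
vector whose first ``d * rnz`` slopes equal ``theta_star`` (the rest zero,
intercept zero); i.i.d. q-normal errors with sigma = 1.  For each trial the
three penalized paths (LASSO/SCAD/MCP) are fitted, a model is selected per
criterion, and two outcomes are recorded: exact support recovery and the
generalization error on a fresh test set of the same size and law (mean
squared prediction error per observation; absolute error and the
median-of-trials summary are also emitted, since for q >= 2 the errors have
infinite variance and the MSE across trials is unstable by construction).

The full factorial design is d in {10, 100} x rnz in {0.2, 0.4, 0.6, 0.8} x
theta_star in {1, 10, 100, 1000}, 32 cases; the default replication scale
here is m=100 trials per case (configurable up to the original 1000).
Per-trial seeds are derived from the master seed through
``numpy.random.SeedSequence(seed, spawn_key=(trial,))`` so trials are
independent and individually re-runnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lqmodel import Coefficients, Dataset, Support
from .qcore import QNormalParams, QSpec, q_normal_sample
from .selection import CRITERIA, cross_validate, evaluate_path, select
from .solver import fit_path, standardize

__all__ = [
    "ExperimentConfig",
    "TrialResult",
    "gen_design",
    "gen_true_theta",
    "gen_response",
    "run_trial",
    "run_experiment",
    "enumerate_cases",
]

PENALTIES = ("lasso", "scad", "mcp")


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the simulation design."""

    q: float = 1.0
    n: int = 100
    d: int = 10
    rnz: float = 0.2
    theta_star: float = 10.0
    m: int = 100
    seed: int = 0
    penalties: tuple = PENALTIES
    criteria: tuple = ("BIC2",)
    include_cv: bool = False
    nlambda: int = 100
    a: float = 3.7
    gamma: float = 3.0
    cv_folds: int = 10

    def __post_init__(self) -> None:
        QSpec(self.q)  # validates the range
        if self.n < 2 or self.d < 1:
            raise ValueError("need n >= 2 and d >= 1")
        if not 0.0 <= self.rnz <= 1.0:
            raise ValueError("rnz must be in [0, 1]")
        k = self.d * self.rnz
        if abs(k - round(k)) > 1e-9:
            raise ValueError(f"d * rnz = {k} is not a whole number")
        bad = set(self.penalties) - set(PENALTIES)
        if bad:
            raise ValueError(f"unknown penalties: {sorted(bad)}")
        bad = set(self.criteria) - set(CRITERIA)
        if bad:
            raise ValueError(f"unknown criteria: {sorted(bad)}")


@dataclass
class TrialResult:
    """Per-(penalty, criterion) outcomes of one trial."""

    trial: int
    records: pd.DataFrame  # columns: penalty, criterion, support, exact, gen_mse, gen_mae


def _trial_rng(seed: int, trial: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(trial, stream)))


def gen_design(n: int, d: int, seed) -> np.ndarray:
    """Standard-normal n x d design, standardized to centered unit-norm columns."""
    import warnings

    if n <= d:
        warnings.warn(f"n={n} <= d={d}: design columns are linearly dependent", RuntimeWarning)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.standard_normal((n, d))
    ds, _ = standardize(raw, np.zeros(n))
    return ds.X[:, 1:]


def gen_true_theta(d: int, rnz: float, theta_star: float) -> Coefficients:
    """Sparse truth: first ``d*rnz`` slopes equal theta_star, zero intercept."""
    k = round(d * rnz)
    slopes = np.zeros(d)
    slopes[:k] = theta_star
    return Coefficients(0.0, slopes)


def gen_response(design: np.ndarray, theta_true: Coefficients, spec: QSpec, seed) -> np.ndarray:
    """``y = theta_0 + X theta + eps`` with i.i.d. q-normal(0, 1, q) errors."""
    n = design.shape[0]
    eps = q_normal_sample(n, QNormalParams(0.0, 1.0), spec, seed)
    return theta_true.intercept + design @ theta_true.slopes + eps


def run_trial(config: ExperimentConfig, trial: int) -> TrialResult:
    """Generate one dataset, fit every penalty path, select, and score."""
    spec = QSpec(config.q)
    theta_true = gen_true_theta(config.d, config.rnz, config.theta_star)
    true_support = theta_true.support()

    design = gen_design(config.n, config.d, _trial_rng(config.seed, trial, 0))
    y = gen_response(design, theta_true, spec, _trial_rng(config.seed, trial, 1))
    X = np.column_stack([np.ones(config.n), design])
    data = Dataset(X, y)

    test_design = gen_design(config.n, config.d, _trial_rng(config.seed, trial, 2))
    y_test = gen_response(test_design, theta_true, spec, _trial_rng(config.seed, trial, 3))
    Xt = np.column_stack([np.ones(config.n), test_design])

    rows = []
    for pen in config.penalties:
        # per-family grids: the all-zero lambda_max differs across penalties
        path = fit_path(data, pen, a=config.a, gamma=config.gamma, nlambda=config.nlambda)
        table = evaluate_path(path, data, spec, criteria=config.criteria, refit_seed=trial)
        chosen: dict[str, tuple[int, Support]] = {}
        for crit in config.criteria:
            try:
                chosen[crit] = select(table, crit)
            except ValueError:
                chosen[crit] = None
        if config.include_cv:
            cv = cross_validate(
                data, pen, a=config.a, gamma=config.gamma, K=config.cv_folds,
                seed=int(_trial_rng(config.seed, trial, 4).integers(2**31)),
                lambdas=path.lambdas,
            )
            chosen["CV"] = (cv.chosen_index, path.coefs[cv.chosen_index].support())
        for crit, pick in chosen.items():
            if pick is None:
                rows.append(dict(penalty=pen, criterion=crit, support=None,
                                 exact=False, gen_mse=np.nan, gen_mae=np.nan))
                continue
            k, supp = pick
            coef = path.coefs[k]
            pred = Xt @ coef.as_array()
            err = y_test - pred
            rows.append(dict(
                penalty=pen,
                criterion=crit,
                support=tuple(supp.sorted()),
                exact=(supp.indices == true_support.indices),
                gen_mse=float(np.mean(err * err)),
                gen_mae=float(np.mean(np.abs(err))),
            ))
    return TrialResult(trial, pd.DataFrame(rows))


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run m trials and aggregate.

    Returns ``(summary, trials)``: the summary has one row per
    (penalty, criterion) with the exact-recovery count and the
    mean/median generalization errors; ``trials`` is the tidy per-trial
    record.  Deterministic given ``config.seed``.
    """
    frames = []
    for t in range(config.m):
        res = run_trial(config, t)
        frame = res.records
        frame.insert(0, "trial", t)
        frames.append(frame)
    trials = pd.concat(frames, ignore_index=True)
    grp = trials.groupby(["penalty", "criterion"], sort=True)
    summary = grp.agg(
        recovered=("exact", "sum"),
        m=("exact", "size"),
        gen_mse_mean=("gen_mse", "mean"),
        gen_mse_median=("gen_mse", "median"),
        gen_mae_mean=("gen_mae", "mean"),
    ).reset_index()
    summary["recovered"] = summary["recovered"].astype(int)
    for key, val in asdict(config).items():
        if key in ("penalties", "criteria"):
            continue
        summary[key] = val
    return summary, trials


def enumerate_cases() -> list[dict]:
    """The 32-cell factorial (rnz outer, d inner, theta_star fastest)."""
    cases = []
    num = 0
    for rnz in (0.2, 0.4, 0.6, 0.8):
        for d in (10, 100):
            for theta_star in (1.0, 10.0, 100.0, 1000.0):
                num += 1
                cases.append(dict(case=num, d=d, rnz=rnz, theta_star=theta_star))
    return cases
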