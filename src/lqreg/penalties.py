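"""Penalty functions (LASSO, SCAD, MCP) and their scalar thresholding operators.

The penalties are separable over slope coordinates (the intercept is never
penalized).  With ``t = |theta_i|``:

* LASSO: ``lambda * t``;
* SCAD (tuning a > 2): ``lambda*t`` for t <= lambda, then
  ``-(t^2 - 2*a*lambda*t + lambda^2) / (2(a-1))``, then constant
  ``(a+1)*lambda^2/2`` beyond ``a*lambda``;
* MCP (tuning gamma > 0): ``lambda * integral_0^t (1 - u/(gamma*lambda))+ du``,
  constant ``gamma*lambda^2/2`` beyond ``gamma*lambda``.

``threshold`` solves the unit-curvature scalar problem
``argmin_theta 0.5*(z - theta)^2 + rho_lambda(theta)`` (soft / firm
thresholding).  ``prox`` generalizes to a penalty weight w,
``argmin 0.5*(z-theta)^2 + w*rho_lambda(theta)``, which the coordinate
descent solver needs because unit-norm design columns give the scalar
subproblem a penalty weight of n.  For weights at which the SCAD/MCP scalar
objective loses strict convexity the minimizer is found by exact candidate
enumeration over the piecewise-quadratic branches, with ties broken toward
smaller |theta| (the sparser solution), deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PenaltySpec", "penalty_value", "threshold", "prox"]

FAMILIES = ("lasso", "scad", "mcp")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family with regularization parameter and tuning constants.

    Defaults a=3.7 (SCAD) and gamma=3 (MCP) are the conventional choices.
    """

    family: str
    lam: float
    a: float = 3.7
    gamma: float = 3.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}; got {self.family!r}")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.family == "scad" and not self.a > 2:
            raise ValueError("SCAD requires a > 2")
        if self.family == "mcp" and not self.gamma > 0:
            raise ValueError("MCP requires gamma > 0")

    def with_lam(self, lam: float) -> "PenaltySpec":
        return PenaltySpec(self.family, lam, self.a, self.gamma)


def _scad_scalar(t: np.ndarray, lam: float, a: float) -> np.ndarray:
    # continuous at t=lam and t=a*lam (the middle branch is read as
    # -(t^2 - 2*a*lam*t + lam^2)/(2(a-1)), the only continuous reading)
    out = np.where(
        t <= lam,
        lam * t,
        np.where(
            t <= a * lam,
            -(t * t - 2.0 * a * lam * t + lam * lam) / (2.0 * (a - 1.0)),
            (a + 1.0) * lam * lam / 2.0,
        ),
    )
    return out


def _mcp_scalar(t: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    # closed form of lam * int_0^t (1 - u/(gamma*lam))+ du
    out = np.where(
        t <= gamma * lam,
        lam * t - t * t / (2.0 * gamma),
        gamma * lam * lam / 2.0,
    )
    return out


def penalty_value(slopes, spec: PenaltySpec) -> float:
    """Separable penalty value ``sum_i rho_lambda(|theta_i|)`` over slopes."""
    t = np.abs(np.asarray(slopes, dtype=float).ravel())
    if spec.lam == 0.0:
        return 0.0
    if spec.family == "lasso":
        vals = spec.lam * t
    elif spec.family == "scad":
        vals = _scad_scalar(t, spec.lam, spec.a)
    else:
        vals = _mcp_scalar(t, spec.lam, spec.gamma)
    return float(vals.sum())


def _scalar_objective(theta: float, z: float, spec: PenaltySpec, w: float) -> float:
    return 0.5 * (z - theta) ** 2 + w * penalty_value([theta], spec)


def _soft(z: float, thr: float) -> float:
    return float(np.sign(z) * max(abs(z) - thr, 0.0))


def prox(z: float, spec: PenaltySpec, weight: float = 1.0) -> float:
    """``argmin_theta 0.5*(z - theta)^2 + weight * rho_lambda(theta)``.

    Exact for every weight > 0; odd in z; |result| <= |z|; identity when
    ``lam == 0``.  Ties (possible for nonconvex SCAD/MCP branches) go to the
    candidate with smaller |theta|.
    """
    z = float(z)
    w = float(weight)
    if w < 0:
        raise ValueError("weight must be >= 0")
    lam = spec.lam
    if lam == 0.0 or w == 0.0:
        return z
    s, az = (1.0 if z >= 0 else -1.0), abs(z)

    if spec.family == "lasso":
        return _soft(z, w * lam)

    # SCAD/MCP: enumerate per-branch stationary points and breakpoints of the
    # piecewise-quadratic objective in t = |theta| >= 0, evaluate, take argmin.
    cands: list[float] = [0.0]
    if spec.family == "mcp":
        g = spec.gamma
        cands.append(g * lam)
        if az > g * lam:
            cands.append(az)
        denom = 1.0 - w / g  # curvature of the inner branch
        if denom > 0:
            t = (az - w * lam) / denom
            if 0.0 < t < g * lam:
                cands.append(t)
    else:  # scad
        a = spec.a
        cands.extend([lam, a * lam])
        t1 = az - w * lam  # branch t <= lam, curvature 1
        if 0.0 < t1 < lam:
            cands.append(t1)
        denom = 1.0 - w / (a - 1.0)  # middle-branch curvature
        if denom > 0:
            t2 = (az - w * a * lam / (a - 1.0)) / denom
            if lam < t2 < a * lam:
                cands.append(t2)
        if az > a * lam:
            cands.append(az)

    best_t, best_val = 0.0, _scalar_objective(0.0, az, spec, w)
    for t in cands[1:]:
        val = _scalar_objective(t, az, spec, w)
        if val < best_val or (val == best_val and t < best_t):
            best_t, best_val = t, val
    return s * best_t


def threshold(z: float, spec: PenaltySpec) -> float:
    """Unit-curvature scalar thresholding: soft (LASSO) / firm (SCAD, MCP).

    For SCAD this requires a > 2 and for MCP gamma > 1 so that the scalar
    objective is strictly convex and the minimizer unique.
    """
    if spec.family == "mcp" and spec.gamma <= 1.0:
        raise ValueError("unit-curvature MCP thresholding requires gamma > 1")
    return prox(z, spec, weight=1.0)
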