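"""q-deformed calculus and the q-normal distribution family.

The q-normal family is a Tsallis-type generalization of the Gaussian built
from the q-exponential ``exp_q(u) = {1 + (1-q)u}^(1/(1-q))``.  For
``1 <= q < 3`` the unit-dispersion density

    f_q(y | xi, sigma) = (1 / (sigma * Z_q)) * exp_q(-((y - xi)/sigma)^2 / (3-q))

is supported on the whole real line: ``q = 1`` recovers the normal
distribution, ``q = 2`` the Cauchy, and generally ``1 < q < 3`` is a scaled
Student-t with ``nu = (3-q)/(q-1)`` degrees of freedom.  This module exposes
the deformed log/exp pair, the q <-> nu correspondence, the density, and
exact sampling through the Student-t equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "QSpec",
    "QNormalParams",
    "log_q",
    "exp_q",
    "nu_of_q",
    "q_normal_pdf",
    "q_normal_sample",
]

# below this distance from q=1 the power-function formulas lose precision
# to cancellation; fall back to the ordinary log/exp branch
_Q_ONE_TOL = 1e-10


def _validate_q(q: float) -> float:
    q = float(q)
    if not (1.0 <= q < 3.0):
        raise ValueError(f"q must lie in [1, 3); got q={q}")
    return q


@dataclass(frozen=True)
class QSpec:
    """The deformation parameter q with its derived constants.

    Attributes
    ----------
    q : float
        Deformation parameter, ``1 <= q < 3``.
    nu : float
        Degrees of freedom of the equivalent Student-t, ``(3-q)/(q-1)``;
        ``inf`` at q=1 (the Gaussian limit).
    Zq : float
        Normalizing constant of the unit-dispersion density:
        ``sqrt(2*pi)`` at q=1, ``sqrt(nu) * B(nu/2, 1/2)`` for q>1.
    """

    q: float
    nu: float = field(init=False)
    Zq: float = field(init=False)

    def __post_init__(self) -> None:
        q = _validate_q(self.q)
        object.__setattr__(self, "q", q)
        if q <= 1.0 + _Q_ONE_TOL:
            nu = math.inf
            zq = math.sqrt(2.0 * math.pi)
        else:
            nu = (3.0 - q) / (q - 1.0)
            zq = math.sqrt(nu) * special.beta(nu / 2.0, 0.5)
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "Zq", zq)

    @property
    def is_gaussian(self) -> bool:
        return math.isinf(self.nu)


@dataclass(frozen=True)
class QNormalParams:
    """Location/dispersion parameters of a q-normal distribution."""

    xi: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")


def log_q(u, q: float):
    """q-logarithm ``(u^(1-q) - 1)/(1-q)``; the natural log at q=1.

    Parameters
    ----------
    u : array_like, positive
    q : float in [1, 3)
    """
    q = _validate_q(q)
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0):
        raise ValueError("log_q requires u > 0")
    if q <= 1.0 + _Q_ONE_TOL:
        out = np.log(u)
    else:
        out = (u ** (1.0 - q) - 1.0) / (1.0 - q)
    return out if out.ndim else float(out)


def exp_q(u, q: float):
    """q-exponential ``{1 + (1-q)u}^(1/(1-q))``; ordinary exp at q=1.

    Inverse of :func:`log_q` on its domain.  For q>1 the argument must
    satisfy ``1 + (1-q)u > 0``, i.e. ``u < 1/(q-1)`` (equivalently
    ``u < -1/(1-q)``, the same bound with the positivity convention made
    explicit).
    """
    q = _validate_q(q)
    u = np.asarray(u, dtype=float)
    if q <= 1.0 + _Q_ONE_TOL:
        out = np.exp(u)
    else:
        base = 1.0 + (1.0 - q) * u
        if np.any(base <= 0):
            raise ValueError(
                "exp_q argument outside the q-exponential domain "
                f"(requires 1 + (1-q)u > 0, i.e. u < {1.0 / (q - 1.0):g} for q={q})"
            )
        out = base ** (1.0 / (1.0 - q))
    return out if out.ndim else float(out)


def nu_of_q(q: float) -> float:
    """Degrees of freedom ``nu = (3-q)/(q-1)`` of the equivalent Student-t.

    Inverse of ``q = 1 + 2/(nu+1)``.  Defined for ``1 < q < 3``; e.g.
    q=13/11 -> nu=10, q=3/2 -> nu=3, q=2 -> nu=1 (Cauchy).
    """
    q = float(q)
    if not (1.0 < q < 3.0):
        raise ValueError(f"nu_of_q requires 1 < q < 3; got q={q}")
    return (3.0 - q) / (q - 1.0)


def q_normal_pdf(y, params: QNormalParams | None = None, spec: QSpec | None = None, *, q: float | None = None):
    """Density of the q-normal distribution.

    Either ``spec`` or the shorthand ``q=`` must be given; ``params``
    defaults to the standard (xi=0, sigma=1) member.  Equals the normal
    density at q=1 and the scaled Student-t density
    ``t_nu((y - xi)/sigma) / sigma`` for 1<q<3.
    """
    if spec is None:
        if q is None:
            raise ValueError("provide spec or q")
        spec = QSpec(q)
    if params is None:
        params = QNormalParams()
    y = np.asarray(y, dtype=float)
    z = (y - params.xi) / params.sigma
    if spec.is_gaussian:
        out = np.exp(-0.5 * z * z) / (params.sigma * spec.Zq)
    else:
        # exp_q(-z^2/(3-q)) = (1 + z^2/nu)^(-(nu+1)/2); always in-domain for q in (1,3)
        out = (1.0 + z * z / spec.nu) ** (-(spec.nu + 1.0) / 2.0) / (params.sigma * spec.Zq)
    return out if out.ndim else float(out)


def q_normal_sample(
    n: int,
    params: QNormalParams | None = None,
    spec: QSpec | None = None,
    seed=None,
    *,
    q: float | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. q-normal variates.

    Uses the exact location-scale Student-t representation
    ``Y = xi + sigma * T`` with ``T`` standard normal (q=1) or Student-t with
    ``nu_of_q(q)`` degrees of freedom (q>1).  ``seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    if spec is None:
        if q is None:
            raise ValueError("provide spec or q")
        spec = QSpec(q)
    if params is None:
        params = QNormalParams()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if spec.is_gaussian:
        t = rng.standard_normal(n)
    else:
        t = rng.standard_t(spec.nu, size=n)
    return params.xi + params.sigma * t
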