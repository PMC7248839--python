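"""Finite-N statistical distributions and their thermodynamic-limit forms.

The exponential weights of classical statistical mechanics arise from
finite counting problems through Euler's limit (1 - x/N)^N -> e^{-x}.
Three routes are implemented:

* occupancy of a subvolume by N particles — binomial, collapsing to the
  Poisson distribution as N, V -> inf at fixed density;
* quanta shared among s harmonic oscillators (stars-and-bars counting) —
  collapsing to the Boltzmann weight as s, M -> inf at fixed M/s;
* the deformed Boltzmann factor (1 - eps*beta/N)^N itself, whose finite-N
  form is the Tsallis-like power law behind the deformed rate law
  (1/N plays the role of the deformation parameter d, and of 1 - q in the
  Tsallis parametrisation).

The Planck-oscillator average energy and the series expansion of its
reciprocal (a transitivity analogue) complete the statistical toolkit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DomainError, InvalidParameterError

__all__ = [
    "OccupancyModel",
    "OscillatorSystem",
    "binomial_occupancy",
    "poisson_limit",
    "binomial_poisson_distance",
    "oscillator_weight",
    "boltzmann_from_counting",
    "counting_beta",
    "deformed_boltzmann",
    "tsallis_q",
    "tsallis_n",
    "planck_average_energy",
    "reciprocal_energy_expansion",
    "euler_convergence_table",
    "poisson_convergence_table",
    "counting_convergence_table",
]

# exact integer combinatorics below this size; log-gamma above
_EXACT_LIMIT = 60


@dataclass(frozen=True)
class OccupancyModel:
    """N particles in volume V; occupancy of a subvolume v is binomial."""

    N: int
    V: float
    v: float

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 1:
            raise InvalidParameterError("N must be an integer >= 1")
        object.__setattr__(self, "N", int(self.N))
        if not self.V > 0 or not 0 < self.v <= self.V:
            raise InvalidParameterError("require V > 0 and 0 < v <= V")

    @property
    def p(self) -> float:
        return self.v / self.V

    @property
    def n_bar(self) -> float:
        return self.N * self.p

    @property
    def density(self) -> float:
        return self.N / self.V


@dataclass(frozen=True)
class OscillatorSystem:
    """s oscillators sharing M quanta of size h_nu (subsystem + reservoir)."""

    s: int
    M: int
    h_nu: float = 1.0

    def __post_init__(self) -> None:
        if int(self.s) != self.s or self.s < 1:
            raise InvalidParameterError("s must be an integer >= 1")
        if int(self.M) != self.M or self.M < 0:
            raise InvalidParameterError("M must be an integer >= 0")
        object.__setattr__(self, "s", int(self.s))
        object.__setattr__(self, "M", int(self.M))
        if not self.h_nu > 0:
            raise InvalidParameterError("h_nu must be positive")

    @property
    def m_bar(self) -> float:
        return self.M / self.s


def binomial_occupancy(model: OccupancyModel, n):
    """Exact binomial pmf for n particles in the subvolume (log-space)."""
    narr = np.asarray(n)
    if np.any(narr < 0) or np.any(narr > model.N):
        raise InvalidParameterError(f"n must lie in 0..{model.N}")
    out = stats.binom.pmf(narr, model.N, model.p)
    return float(out) if np.ndim(n) == 0 else out


def poisson_limit(n_bar: float, n):
    """Poisson pmf, the N -> inf occupancy limit at fixed mean n_bar."""
    if n_bar < 0:
        raise InvalidParameterError("n_bar must be non-negative")
    narr = np.asarray(n)
    if np.any(narr < 0):
        raise InvalidParameterError("n must be non-negative")
    out = stats.poisson.pmf(narr, n_bar)
    return float(out) if np.ndim(n) == 0 else out


def binomial_poisson_distance(model: OccupancyModel) -> float:
    """Total-variation distance between the occupancy pmf and its Poisson limit."""
    support = np.arange(model.N + 1)
    pb = binomial_occupancy(model, support)
    pp = poisson_limit(model.n_bar, support)
    tail = 1.0 - pp.sum()  # Poisson mass beyond n = N
    return 0.5 * (np.abs(pb - pp).sum() + max(tail, 0.0))


def oscillator_weight(s: int, m: int):
    """Number of ways W(s, m) = C(s+m-1, m) to share m quanta among s oscillators.

    Exact integer arithmetic for s+m <= 60, log-gamma above (returned as
    float in that regime).
    """
    if s < 1 or m < 0:
        raise InvalidParameterError("require s >= 1 and m >= 0")
    if s + m <= _EXACT_LIMIT:
        return math.comb(s + m - 1, m)
    return math.exp(gammaln(s + m) - gammaln(m + 1) - gammaln(s))


def boltzmann_from_counting(system: OscillatorSystem, n):
    """Probability that the subsystem holds n quanta.

    P(n) = W(s, M-n) / sum_{j=0}^{M} W(s, M-j); the denominator is the
    finite total-energy-constrained sum, which collapses to C(s+M, M).
    In the limit s, M -> inf at fixed m_bar = M/s the ratio
    P(n+1)/P(n) -> m_bar/(1+m_bar), i.e. the Boltzmann factor e^{-h_nu*beta}
    with beta defined by that ratio (see :func:`counting_beta`).
    """
    narr = np.atleast_1d(np.asarray(n))
    if np.any(narr < 0) or np.any(narr != np.floor(narr)):
        raise InvalidParameterError("n must be a non-negative integer")
    narr = narr.astype(int)
    s, M = system.s, system.M
    out = np.zeros(narr.shape, dtype=float)
    inside = narr <= M
    if s + M <= _EXACT_LIMIT:
        denom = math.comb(s + M, M)
        vals = [math.comb(s + M - k - 1, M - k) / denom for k in narr[inside]]
        out[inside] = vals
    else:
        k = narr[inside]
        log_denom = gammaln(s + M + 1) - gammaln(M + 1) - gammaln(s + 1)
        log_w = gammaln(s + M - k) - gammaln(M - k + 1) - gammaln(s)
        out[inside] = np.exp(log_w - log_denom)
    return float(out[0]) if np.ndim(n) == 0 else out


def counting_beta(system: OscillatorSystem) -> float:
    """Coldness implied by the limiting ratio e^{-h_nu*beta} = m_bar/(1+m_bar)."""
    if system.M == 0:
        raise InvalidParameterError("beta is undefined for M = 0 (zero quanta)")
    return math.log1p(1.0 / system.m_bar) / system.h_nu


def deformed_boltzmann(N: float, x):
    """Finite-N Boltzmann factor (1 - x/N)^N; pointwise -> e^{-x} as N -> inf.

    N may be any positive real (the deformation d = 1/N of the deformed
    rate law); the domain requires x < N.
    """
    if not N > 0:
        raise InvalidParameterError("N must be positive")
    xarr = np.asarray(x, dtype=float)
    if np.any(xarr >= N):
        raise DomainError(f"dimensionless energy x must lie below N = {N}")
    out = (1.0 - xarr / N) ** N
    return float(out) if np.ndim(x) == 0 else out


def tsallis_q(N: float) -> float:
    """Tsallis entropic index q = 1 - 1/N of the finite-N factor."""
    if N == 0:
        raise InvalidParameterError("N must be non-zero")
    return 1.0 - 1.0 / N


def tsallis_n(q: float) -> float:
    """Inverse mapping N = 1/(1-q); round-trips with :func:`tsallis_q`."""
    if q == 1:
        return math.inf
    return 1.0 / (1.0 - q)


def planck_average_energy(h_nu: float, beta):
    """Average energy h_nu/(e^{h_nu*beta} - 1) of a Planck oscillator."""
    if not h_nu > 0:
        raise InvalidParameterError("h_nu must be positive")
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0):
        raise InvalidParameterError("beta must be positive")
    out = h_nu / np.expm1(h_nu * b)
    return float(out) if np.ndim(beta) == 0 else out


def reciprocal_energy_expansion(h_nu: float, beta, order: int = 4):
    """Truncated power series for the reciprocal average energy.

    The exact reciprocal is 1/E = (e^{h_nu*beta} - 1)/h_nu, whose series is
    (1/h_nu) * sum_{j=1}^{order} (h_nu*beta)^j / j! with truncation error
    O((h_nu*beta)^{order+1}) — the low-temperature power law in beta that
    plays the role of a transitivity function for the Planck oscillator.
    (Statements of this expansion sometimes carry an extra constant term
    1/h_nu, i.e. they expand e^x/h_nu; the difference is asymptotically
    negligible as beta grows but breaks exactness at small beta, so the
    constant is omitted here.)
    """
    if not h_nu > 0:
        raise InvalidParameterError("h_nu must be positive")
    if not 1 <= order <= 4:
        raise InvalidParameterError("order must be between 1 and 4")
    b = np.asarray(beta, dtype=float)
    if np.any(b < 0):
        raise InvalidParameterError("beta must be non-negative")
    x = h_nu * b
    total = np.zeros_like(x)
    term = np.ones_like(x)
    for j in range(1, order + 1):
        term = term * x / j
        total = total + term
    out = total / h_nu
    return float(out) if np.ndim(beta) == 0 else out


# ---------------------------------------------------------------------------
# convergence reports (exportable as CSV via pandas)
# ---------------------------------------------------------------------------


def euler_convergence_table(N_values, x_max: float = 5.0, num: int = 501) -> pd.DataFrame:
    """Sup-norm distance between (1-x/N)^N and e^{-x} on [0, x_max] per N."""
    x = np.linspace(0.0, x_max, num)
    target = np.exp(-x)
    rows = []
    for N in N_values:
        if x_max >= N:
            raise DomainError(f"x grid must lie below N = {N}")
        rows.append(
            {"N": N, "sup_norm": float(np.max(np.abs(deformed_boltzmann(N, x) - target)))}
        )
    return pd.DataFrame(rows)


def poisson_convergence_table(N_values, n_bar: float, V: float = 1.0) -> pd.DataFrame:
    """Total-variation distance binomial(N) vs Poisson at fixed mean n_bar."""
    rows = []
    for N in N_values:
        model = OccupancyModel(N=N, V=V, v=V * n_bar / N)
        rows.append({"N": N, "tv_distance": binomial_poisson_distance(model)})
    return pd.DataFrame(rows)


def counting_convergence_table(scales, m_bar: float = 1.0, h_nu: float = 1.0) -> pd.DataFrame:
    """Error of P(1)/P(0) against the limiting ratio m_bar/(1+m_bar) per scale s."""
    target = m_bar / (1.0 + m_bar)
    rows = []
    for s in scales:
        system = OscillatorSystem(s=int(s), M=int(round(m_bar * s)), h_nu=h_nu)
        p0 = boltzmann_from_counting(system, 0)
        p1 = boltzmann_from_counting(system, 1)
        rows.append({"s": int(s), "ratio_error": abs(p1 / p0 - target)})
    return pd.DataFrame(rows)
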