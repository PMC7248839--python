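"""Closed-form rate laws, activation energies and transitivity functions.

Rate-constant data admit two complementary representations.  The Arrhenius
plane plots ln k against the coldness beta = 1/(kB*T); the apparent
activation energy is the Tolman/IUPAC logarithmic derivative

    Ea(beta) = -d ln k / d beta .

The transitivity plane plots its reciprocal, gamma(beta) = 1/Ea(beta),
against beta.  The deformed exponential law

    k(beta) = A * (1 - d * eps * beta)**(1/d)

(the Aquilanti-Mundim, "AM", law) makes gamma exactly linear in beta with
slope -d and intercept 1/eps; d -> 0 recovers Arrhenius (gamma constant),
d < 0 describes sub-Arrhenius (quantum-tunneling) concavity, d > 0
super-Arrhenius convexity with a finite lower thermal limit T-dagger where
the process shuts down.  The generalized transitivity law

    gamma(beta) = (1/eps) * (1 - beta/beta_dagger)**zeta

unifies these: the universality exponent zeta = 0, 1, 2 generates the
Arrhenius, AM and Vogel-Fulcher-Tammann laws respectively.  A finite-sum
unimolecular model in the Fowler-Guggenheim tradition, with the activation
energy accumulated over s internal oscillators, gives a rate law expressible
through the upper incomplete gamma function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import ClassVar, Union

import numpy as np
from scipy import integrate, special

from .errors import (
    DomainError,
    InvalidParameterError,
    NoFiniteLimitError,
    NotApplicableError,
    NumericalError,
    SingularTransitivityError,
)
from .units import UnitSystem

__all__ = [
    "ArrheniusParams",
    "AMParams",
    "VFTParams",
    "FGParams",
    "ZetaParams",
    "ThermalLimits",
    "RateLawModel",
    "make_model",
    "k_arrhenius",
    "k_am",
    "k_vft",
    "k_fg_series",
    "k_fg_closed",
    "rate",
    "log_rate",
    "activation_energy",
    "numerical_activation_energy",
    "transitivity",
    "rate_from_transitivity",
    "am_expansion",
    "d_from_tunneling",
    "thermal_limits",
    "wigner_asymptote_residual",
]


def _as_beta(beta, *, allow_negative: bool = False):
    b = np.asarray(beta, dtype=float)
    if not allow_negative and np.any(b < 0):
        raise DomainError("coldness beta must be non-negative")
    return b, b.ndim == 0


def _out(values, scalar: bool):
    arr = np.asarray(values, dtype=float)
    return float(arr) if scalar else arr


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrheniusParams:
    """Classical Arrhenius law k = A*exp(-eps_act*beta)."""

    A: float
    eps_act: float
    law: ClassVar[str] = "arrhenius"

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise InvalidParameterError("pre-exponential A must be positive")


@dataclass(frozen=True)
class AMParams:
    """Deformed-exponential (Aquilanti-Mundim) law k = A*(1-d*eps*beta)^(1/d).

    ``d`` is the deformation parameter: d = 0 is exact Arrhenius, d < 0
    sub-Arrhenius (quantum propensity), d > 0 super-Arrhenius (classical,
    collective propensity).  ``eps_act`` may be negative together with d > 0
    for the rarer anti-Arrhenius behaviour.
    """

    A: float
    eps_act: float
    d: float
    law: ClassVar[str] = "am"

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise InvalidParameterError("pre-exponential A must be positive")

    @property
    def beta_dagger(self) -> float:
        """Domain boundary 1/(d*eps_act); +inf when no boundary at beta>=0."""
        prod = self.d * self.eps_act
        return 1.0 / prod if prod > 0 else np.inf


@dataclass(frozen=True)
class VFTParams:
    """Vogel-Fulcher-Tammann law k = A*exp(-eps*beta/(1-beta/beta_dagger))."""

    A: float
    eps_act: float
    beta_dagger: float
    law: ClassVar[str] = "vft"

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise InvalidParameterError("pre-exponential A must be positive")
        if not self.eps_act > 0:
            raise InvalidParameterError("VFT activation energy must be positive")
        if not self.beta_dagger > 0:
            raise InvalidParameterError("beta_dagger must be positive")


@dataclass(frozen=True)
class FGParams:
    """Unimolecular rate law with energy pooled over s internal oscillators.

    k = A * exp(-x) * sum_{r=0}^{s-1} x^r / r!  with x = eps_act*beta,
    equivalently A * Gamma(s, x)/Gamma(s); s = 1 reduces to Arrhenius.
    """

    A: float
    eps_act: float
    s: int
    law: ClassVar[str] = "fg"

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise InvalidParameterError("pre-exponential A must be positive")
        if not self.eps_act > 0:
            raise InvalidParameterError("activation energy must be positive")
        if int(self.s) != self.s or self.s < 1:
            raise InvalidParameterError("s must be an integer >= 1")
        object.__setattr__(self, "s", int(self.s))


@dataclass(frozen=True)
class ZetaParams:
    """Generalized transitivity law gamma = (1/eps)*(1-beta/beta_dagger)^zeta.

    The rate law follows by integrating 1/gamma: ln k = ln A - int_0^beta
    Ea(b') db'.  zeta = 0, 1, 2 reproduce Arrhenius, AM and VFT.  The
    reference coldness of the general asymptotic form is fixed at
    beta0 = 0, where gamma(0) = alpha = 1/eps_act.
    """

    A: float
    eps_act: float
    beta_dagger: float
    zeta: float
    law: ClassVar[str] = "zeta"
    beta0: ClassVar[float] = 0.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise InvalidParameterError("pre-exponential A must be positive")
        if self.eps_act == 0:
            raise InvalidParameterError("eps_act must be non-zero")
        if self.zeta < 0:
            raise InvalidParameterError("zeta must be >= 0")
        if self.zeta > 0 and not self.beta_dagger > 0:
            raise InvalidParameterError("beta_dagger must be positive for zeta > 0")

    @property
    def alpha(self) -> float:
        return 1.0 / self.eps_act


RateLawModel = Union[ArrheniusParams, AMParams, VFTParams, FGParams, ZetaParams]

_LAW_CLASSES = {
    "arrhenius": ArrheniusParams,
    "am": AMParams,
    "vft": VFTParams,
    "fg": FGParams,
    "zeta": ZetaParams,
}


def make_model(law: str, params: dict) -> RateLawModel:
    """Build a parameter object from a law tag and a plain mapping."""
    try:
        cls = _LAW_CLASSES[law]
    except KeyError:
        raise InvalidParameterError(
            f"unknown law {law!r}; expected one of {sorted(_LAW_CLASSES)}"
        ) from None
    fields = {f for f in cls.__dataclass_fields__}
    extra = set(params) - fields
    if extra:
        raise InvalidParameterError(f"unexpected parameters for {law}: {sorted(extra)}")
    try:
        return cls(**params)
    except TypeError as exc:
        raise InvalidParameterError(str(exc)) from None


@dataclass(frozen=True)
class ThermalLimits:
    """Lower thermal limit of a super-Arrhenius process.

    eps_dagger = d*eps_act is the threshold thermal energy, T_dagger the
    minimum operative temperature and beta_dagger = 1/eps_dagger the
    coldness at which the deformed rate law vanishes.
    """

    eps_dagger: float
    T_dagger: float
    beta_dagger: float
    units: UnitSystem

    def __post_init__(self) -> None:
        if abs(self.eps_dagger * self.beta_dagger - 1.0) > 1e-12:
            raise InvalidParameterError("beta_dagger must equal 1/eps_dagger")
        kb = self.units.boltzmann_constant
        if abs(self.eps_dagger - kb * self.T_dagger) > 1e-12 * abs(self.eps_dagger):
            raise InvalidParameterError("eps_dagger must equal kB*T_dagger")


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------


def k_arrhenius(params, beta):
    """Arrhenius rate A*exp(-eps_act*beta); strictly positive."""
    b, scalar = _as_beta(beta)
    return _out(params.A * np.exp(-params.eps_act * b), scalar)


def k_am(params: AMParams, beta, *, strict_domain: bool = False):
    """Deformed-exponential rate A*(1 - d*eps*beta)^(1/d).

    At exactly beta = beta_dagger (super-Arrhenius, 1/d > 0) the continuous
    extension k = 0 is returned unless ``strict_domain`` is set, in which
    case the boundary also raises :class:`DomainError`.
    """
    b, scalar = _as_beta(beta)
    d = params.d
    if d == 0:
        return _out(params.A * np.exp(-params.eps_act * b), scalar)
    u = 1.0 - d * params.eps_act * b
    limit = np.any(u < 0) or (strict_domain and np.any(u <= 0))
    if limit or (np.any(u <= 0) and 1.0 / d < 0):
        raise DomainError(
            "beta beyond the thermal limit beta_dagger = "
            f"{params.beta_dagger:.6g} of the deformed law"
        )
    # log1p keeps full precision for |d| down to the Arrhenius limit
    with np.errstate(divide="ignore"):
        ln_u = np.log1p(-d * params.eps_act * b)
    return _out(params.A * np.exp(ln_u / d), scalar)


def k_vft(params: VFTParams, beta):
    """VFT rate A*exp(-eps*beta/(1-beta/beta_dagger)), valid for beta < beta_dagger."""
    b, scalar = _as_beta(beta)
    if np.any(b >= params.beta_dagger):
        raise DomainError(
            f"beta must lie below beta_dagger = {params.beta_dagger:.6g}"
        )
    return _out(
        params.A * np.exp(-params.eps_act * b / (1.0 - b / params.beta_dagger)), scalar
    )


def k_fg_series(params: FGParams, beta):
    """Finite-sum unimolecular rate A*e^{-x} * sum_{r<s} x^r/r!, x = eps*beta."""
    b, scalar = _as_beta(beta)
    x = params.eps_act * b
    term = np.ones_like(x)
    total = np.ones_like(x)
    for r in range(1, params.s):
        term = term * x / r
        total = total + term
    return _out(params.A * np.exp(-x) * total, scalar)


def k_fg_closed(params: FGParams, beta):
    """Incomplete-gamma closed form A*Gamma(s, eps*beta)/Gamma(s)."""
    b, scalar = _as_beta(beta)
    x = params.eps_act * b
    return _out(params.A * special.gammaincc(params.s, x), scalar)


def log_rate(model: RateLawModel, beta):
    """ln k(beta) for any supported law (stable for fitting in log space)."""
    b, scalar = _as_beta(beta)
    lnA = np.log(model.A)
    if isinstance(model, ArrheniusParams):
        val = lnA - model.eps_act * b
    elif isinstance(model, AMParams):
        if model.d == 0:
            val = lnA - model.eps_act * b
        else:
            u = 1.0 - model.d * model.eps_act * b
            if np.any(u <= 0):
                raise DomainError(
                    "beta at or beyond the thermal limit beta_dagger = "
                    f"{model.beta_dagger:.6g}"
                )
            val = lnA + np.log1p(-model.d * model.eps_act * b) / model.d
    elif isinstance(model, VFTParams):
        if np.any(b >= model.beta_dagger):
            raise DomainError(
                f"beta must lie below beta_dagger = {model.beta_dagger:.6g}"
            )
        val = lnA - model.eps_act * b / (1.0 - b / model.beta_dagger)
    elif isinstance(model, FGParams):
        x = model.eps_act * b
        val = lnA + np.log(special.gammaincc(model.s, x))
    elif isinstance(model, ZetaParams):
        val = np.log(rate_from_transitivity(model, b))
    else:
        raise InvalidParameterError(f"unsupported model {type(model).__name__}")
    return _out(val, scalar)


def rate(model: RateLawModel, beta):
    """k(beta) for any supported law."""
    if isinstance(model, AMParams):
        return k_am(model, beta)
    if isinstance(model, ZetaParams):
        return rate_from_transitivity(model, beta)
    b, scalar = _as_beta(beta)
    return _out(np.exp(log_rate(model, b)), scalar)


# ---------------------------------------------------------------------------
# activation energy and transitivity
# ---------------------------------------------------------------------------


def activation_energy(model: RateLawModel, beta):
    """Apparent activation energy Ea(beta) = -d ln k/d beta, closed form."""
    b, scalar = _as_beta(beta)
    if isinstance(model, ArrheniusParams):
        val = np.full_like(b, model.eps_act, dtype=float)
    elif isinstance(model, AMParams):
        u = 1.0 - model.d * model.eps_act * b
        if np.any(u <= 0):
            raise DomainError(
                "beta at or beyond the thermal limit beta_dagger = "
                f"{model.beta_dagger:.6g}"
            )
        val = model.eps_act / u
    elif isinstance(model, VFTParams):
        if np.any(b >= model.beta_dagger):
            raise DomainError(
                f"beta must lie below beta_dagger = {model.beta_dagger:.6g}"
            )
        val = model.eps_act / (1.0 - b / model.beta_dagger) ** 2
    elif isinstance(model, FGParams):
        x = model.eps_act * b
        q = special.gammaincc(model.s, x)  # Gamma(s,x)/Gamma(s)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (
                model.eps_act
                * x ** (model.s - 1)
                * np.exp(-x)
                / (q * special.gamma(model.s))
            )
        val = np.where(x == 0, model.eps_act if model.s == 1 else 0.0, val)
    elif isinstance(model, ZetaParams):
        if model.zeta > 0 and np.any(b >= model.beta_dagger):
            raise DomainError(
                f"beta must lie below beta_dagger = {model.beta_dagger:.6g}"
            )
        val = model.eps_act * (1.0 - b / model.beta_dagger) ** (-model.zeta) \
            if model.zeta > 0 else np.full_like(b, model.eps_act, dtype=float)
    else:
        raise InvalidParameterError(f"unsupported model {type(model).__name__}")
    return _out(val, scalar)


def numerical_activation_energy(log_rate_fn, beta, *, rel_step=1e-4, min_step=1e-6):
    """Central-difference -d(ln k)/d(beta) with adaptive step.

    The step is max(min_step, rel_step*|beta|); used as an independent check
    of the closed forms and for models supplied only as callables.
    """
    b, scalar = _as_beta(beta)
    h = np.maximum(min_step, rel_step * np.abs(b))
    val = -(np.asarray(log_rate_fn(b + h)) - np.asarray(log_rate_fn(b - h))) / (2 * h)
    return _out(val, scalar)


def transitivity(model: RateLawModel, beta):
    """Transitivity gamma(beta) = 1/Ea(beta).

    For the AM law the exact linear form gamma = 1/eps - d*beta is used so
    the slope/intercept identities hold to machine precision.
    """
    b, scalar = _as_beta(beta)
    if isinstance(model, AMParams):
        if model.eps_act == 0:
            raise SingularTransitivityError("Ea vanishes identically for eps_act = 0")
        if np.any(1.0 - model.d * model.eps_act * b <= 0):
            raise DomainError(
                "beta at or beyond the thermal limit beta_dagger = "
                f"{model.beta_dagger:.6g}"
            )
        return _out(1.0 / model.eps_act - model.d * b, scalar)
    ea = np.asarray(activation_energy(model, b), dtype=float)
    if np.any(ea == 0):
        raise SingularTransitivityError("apparent activation energy vanishes")
    return _out(1.0 / ea, scalar)


# ---------------------------------------------------------------------------
# generalized transitivity law -> rate law
# ---------------------------------------------------------------------------


def rate_from_transitivity(model: ZetaParams, beta):
    """Rate law reconstructed from the generalized transitivity power law.

    ln k(beta) = ln A - int_0^beta [1/gamma(b')] db'.  Closed forms are used
    for zeta in {0, 1, 2}; other exponents fall back to adaptive quadrature
    (absolute/relative tolerance 1e-10).
    """
    b, scalar = _as_beta(beta)
    z, eps, bd = model.zeta, model.eps_act, model.beta_dagger
    if z > 0 and np.any(b >= bd):
        raise DomainError(f"beta must lie below beta_dagger = {bd:.6g}")
    lnA = np.log(model.A)
    if z == 0:
        lnk = lnA - eps * b
    elif z == 1:
        lnk = lnA + eps * bd * np.log1p(-b / bd)
    elif z == 2:
        lnk = lnA - eps * b / (1.0 - b / bd)
    else:
        flat = np.atleast_1d(b)
        integrals = np.empty_like(flat)
        for i, bi in enumerate(flat):
            val, err = integrate.quad(
                lambda u: (1.0 - u / bd) ** (-z),
                0.0,
                bi,
                epsabs=1e-10,
                epsrel=1e-10,
                limit=200,
            )
            if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)):
                raise NumericalError(
                    f"quadrature for zeta={z} did not converge at beta={bi}"
                )
            integrals[i] = val
        lnk = lnA - eps * integrals.reshape(np.shape(b))
    return _out(np.exp(lnk), scalar)


# ---------------------------------------------------------------------------
# expansions, tunneling, limits
# ---------------------------------------------------------------------------


def am_expansion(params: AMParams, beta, order: int = 4):
    """Truncated expansion of the deformed law about the Arrhenius factor.

    k = A e^{-x} [1 - (d/2) x^2 - (d^2/3) x^3 - ((2d-1) d^2/8) x^4 + O(x^5)]
    with x = eps_act*beta; the truncation error of the order-4 form scales
    as x^5.  Orders 0..4 are supported (orders < 2 keep only A e^{-x}).
    """
    if not 0 <= order <= 4:
        raise InvalidParameterError("order must be between 0 and 4")
    b, scalar = _as_beta(beta)
    d = params.d
    x = params.eps_act * b
    if np.any(np.abs(d * x) >= 1):
        raise DomainError("expansion requires |d*eps_act*beta| < 1")
    corr = np.ones_like(x)
    if order >= 2:
        corr = corr - 0.5 * d * x**2
    if order >= 3:
        corr = corr - (d**2 / 3.0) * x**3
    if order >= 4:
        corr = corr - ((2.0 * d - 1.0) * d**2 / 8.0) * x**4
    return _out(params.A * np.exp(-x) * corr, scalar)


def d_from_tunneling(nu_dagger: float, eps_act: float, h: float) -> float:
    """Small-tunneling deformation d = -(1/3)*(h*nu_dagger/(2*eps_act))^2.

    ``nu_dagger`` is the barrier-crossing frequency and ``h`` the Planck
    constant in the unit system of ``eps_act`` (see
    :data:`transitivity.units.PLANCK_CONSTANTS`).  Always non-positive:
    tunneling gives sub-Arrhenius concavity.
    """
    if not eps_act > 0:
        raise InvalidParameterError("barrier height eps_act must be positive")
    if nu_dagger < 0:
        raise InvalidParameterError("barrier frequency must be non-negative")
    return -((h * nu_dagger / (2.0 * eps_act)) ** 2) / 3.0


def thermal_limits(params: AMParams, units: UnitSystem | None = None) -> ThermalLimits:
    """Thermal limit of a super-Arrhenius deformed law (d > 0, eps_act > 0).

    eps_dagger = d*eps_act, T_dagger = eps_dagger/kB, beta_dagger =
    1/(d*eps_act); the rate vanishes at beta_dagger.
    """
    units = units or UnitSystem()
    if params.d <= 0 or params.eps_act <= 0:
        raise NoFiniteLimitError(
            "only super-Arrhenius laws (d > 0, eps_act > 0) have a finite "
            "lower thermal limit"
        )
    eps_dagger = params.d * params.eps_act
    return ThermalLimits(
        eps_dagger=eps_dagger,
        T_dagger=eps_dagger / units.boltzmann_constant,
        beta_dagger=1.0 / eps_dagger,
        units=units,
    )


def wigner_asymptote_residual(params: AMParams, beta):
    """Ratio of the sub-Arrhenius deformed rate to its power-law asymptote.

    For d < 0 the deformed law approaches A*(|d|*eps)^{1/d} * beta^{1/d} as
    beta grows (the Wigner-threshold power law); the returned residual tends
    to 1 monotonically from below/above depending on sign of eps_act.
    """
    if params.d >= 0:
        raise NotApplicableError("power-law asymptote applies only for d < 0")
    b, scalar = _as_beta(beta)
    if np.any(b <= 0):
        raise DomainError("beta must be positive for the asymptote diagnostic")
    inv_d = 1.0 / params.d
    asym = params.A * (abs(params.d) * params.eps_act) ** inv_d * b**inv_d
    return _out(np.asarray(k_am(params, b)) / asym, scalar)
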