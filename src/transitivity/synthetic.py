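"""Seeded generation of rate datasets with known ground truth.

Emulates experimentally (or computationally) determined rate-constant
tables: a temperature grid inside the law's domain, exact rates from one of
the closed-form laws, and multiplicative lognormal noise — i.e. additive
Gaussian noise of relative standard deviation sigma on ln k, which matches
the log-space objective used throughout the fitting module.  Identical
spec + seed always reproduce the dataset bit for bit.

A two-regime construction joins two deformed (AM) laws at a crossover
coldness beta_c with both the transitivity and the rate continuous there,
emulating kinetic data whose transitivity plot shows two straight lines
meeting at a crossover temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import laws
from .errors import DomainError, InvalidSpecError
from .fitting import RateDataset, TransitivityCurve
from .units import UnitSystem

__all__ = [
    "SyntheticSpec",
    "generate",
    "matched_am_segment",
    "generate_two_regime",
    "generate_transitivity",
    "generate_two_regime_transitivity",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic rate dataset.

    ``grid`` selects equal spacing in temperature ("T") or in coldness
    ("beta") between ``t_min`` and ``t_max`` kelvin; ``noise_sigma`` is the
    relative standard deviation of the multiplicative lognormal noise.
    """

    law: str
    params: dict
    t_min: float
    t_max: float
    n: int = 30
    grid: str = "T"
    noise_sigma: float = 0.0
    seed: int = 0
    units: UnitSystem = field(default_factory=UnitSystem)

    def __post_init__(self) -> None:
        if not 0 < self.t_min < self.t_max:
            raise InvalidSpecError("require 0 < t_min < t_max")
        if self.n < 3:
            raise InvalidSpecError("need at least 3 grid points")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        if self.grid not in ("T", "beta"):
            raise InvalidSpecError("grid must be 'T' or 'beta'")
        self.model()  # validates the law tag and parameters

    def model(self) -> laws.RateLawModel:
        return laws.make_model(self.law, self.params)

    def beta_grid(self) -> np.ndarray:
        """Strictly increasing coldness grid (i.e. temperature descending)."""
        if self.grid == "T":
            t = np.linspace(self.t_max, self.t_min, self.n)
            return np.asarray(self.units.beta(t))
        b_lo = self.units.beta(self.t_max)
        b_hi = self.units.beta(self.t_min)
        return np.linspace(b_lo, b_hi, self.n)

    def to_dict(self) -> dict:
        return {
            "law": self.law,
            "params": dict(self.params),
            "t_min": self.t_min,
            "t_max": self.t_max,
            "n": self.n,
            "grid": self.grid,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "units": self.units.to_dict(),
        }


def _check_domain(model, beta, units: UnitSystem) -> None:
    bd = getattr(model, "beta_dagger", np.inf)
    if isinstance(model, laws.AMParams):
        bad = beta >= bd
    elif isinstance(model, (laws.VFTParams, laws.ZetaParams)):
        bad = beta >= bd if getattr(model, "zeta", 1) > 0 else np.zeros_like(beta, bool)
    else:
        bad = np.zeros_like(beta, dtype=bool)
    if np.any(bad):
        temps = np.asarray(units.temperature(beta[bad]))
        raise DomainError(
            "temperature grid crosses the thermal limit "
            f"(beta_dagger = {bd:.6g}): offending temperatures (K) "
            f"{np.array2string(temps, precision=2)}"
        )


def generate(spec: SyntheticSpec) -> RateDataset:
    """Rates k_i = law(beta_i) * exp(sigma * z_i) with seeded standard normals."""
    beta = spec.beta_grid()
    model = spec.model()
    _check_domain(model, beta, spec.units)
    lnk = np.asarray(laws.log_rate(model, beta), dtype=float)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        lnk = lnk + spec.noise_sigma * rng.standard_normal(beta.size)
    return RateDataset(beta=beta, k=np.exp(lnk), units=spec.units)


def matched_am_segment(params_a: laws.AMParams, beta_c: float,
                       d_b: float) -> laws.AMParams:
    """AM parameters for a second regime meeting the first at beta_c.

    The transitivity lines gamma = 1/eps - d*beta of the two regimes are
    constrained to intersect at beta_c, fixing the second activation energy;
    the second prefactor is set so ln k is continuous at beta_c as well.
    """
    gamma_c = 1.0 / params_a.eps_act - params_a.d * beta_c
    inv_eps_b = gamma_c + d_b * beta_c
    if inv_eps_b == 0:
        raise InvalidSpecError("second regime would have infinite activation energy")
    eps_b = 1.0 / inv_eps_b
    lnk_c = laws.log_rate(params_a, beta_c)
    if d_b == 0:
        ln_a_b = lnk_c + eps_b * beta_c
    else:
        u = 1.0 - d_b * eps_b * beta_c
        if u <= 0:
            raise InvalidSpecError("beta_c lies beyond the second regime's limit")
        ln_a_b = lnk_c - np.log(u) / d_b
    return laws.AMParams(A=float(np.exp(ln_a_b)), eps_act=float(eps_b), d=float(d_b))


def generate_two_regime(spec_a: SyntheticSpec, spec_b: SyntheticSpec,
                        beta_c: float) -> RateDataset:
    """Piecewise-AM dataset: regime A for beta <= beta_c, regime B beyond.

    Both specs must carry AM laws whose transitivity lines intersect at
    ``beta_c`` (checked to 1e-8 relative); regime B's prefactor is adjusted
    so that ln k is continuous at the crossover.  Noise and seed are taken
    from ``spec_a``.
    """
    if spec_a.law != "am" or spec_b.law != "am":
        raise InvalidSpecError("two-regime construction requires AM laws")
    model_a = spec_a.model()
    model_b = spec_b.model()
    gam_a = 1.0 / model_a.eps_act - model_a.d * beta_c
    gam_b = 1.0 / model_b.eps_act - model_b.d * beta_c
    scale = max(abs(gam_a), abs(gam_b), 1e-300)
    if abs(gam_a - gam_b) > 1e-8 * scale:
        raise InvalidSpecError(
            "transitivity lines do not intersect at beta_c: "
            f"gamma_A({beta_c:.6g}) = {gam_a:.6g} vs gamma_B = {gam_b:.6g}"
        )
    # enforce rate continuity by re-anchoring B's prefactor
    model_b = matched_am_segment(model_a, beta_c, model_b.d)

    beta_a = spec_a.beta_grid()
    beta_b = spec_b.beta_grid()
    beta = np.concatenate([beta_a[beta_a <= beta_c], beta_b[beta_b > beta_c]])
    if beta.size < 3 or np.any(np.diff(beta) <= 0):
        raise InvalidSpecError("segment grids do not form an increasing beta grid")
    _check_domain(model_a, beta[beta <= beta_c], spec_a.units)
    _check_domain(model_b, beta[beta > beta_c], spec_a.units)
    mask_a = beta <= beta_c
    lnk = np.empty(beta.size, dtype=float)
    lnk[mask_a] = laws.log_rate(model_a, beta[mask_a])
    lnk[~mask_a] = laws.log_rate(model_b, beta[~mask_a])
    if spec_a.noise_sigma > 0:
        rng = np.random.default_rng(spec_a.seed)
        lnk = lnk + spec_a.noise_sigma * rng.standard_normal(beta.size)
    return RateDataset(beta=beta, k=np.exp(lnk), units=spec_a.units)


def _noisy_curve(beta, gamma, sigma, seed, units) -> TransitivityCurve:
    if sigma > 0:
        rng = np.random.default_rng(seed)
        gamma = gamma * np.exp(sigma * rng.standard_normal(beta.size))
    valid = gamma != 0
    ea = np.full_like(gamma, np.nan)
    ea[valid] = 1.0 / gamma[valid]
    return TransitivityCurve(beta=beta, ea=ea, gamma=gamma, valid=valid,
                             method="synthetic", units=units)


def generate_transitivity(spec: SyntheticSpec) -> TransitivityCurve:
    """Transitivity curve sampled from a law's closed-form gamma(beta).

    The noise model acts multiplicatively on gamma itself — emulating
    transitivity values extracted point by point from independent activation
    energy determinations, with relative standard deviation
    ``spec.noise_sigma``.
    """
    beta = spec.beta_grid()
    model = spec.model()
    _check_domain(model, beta, spec.units)
    gamma = np.asarray(laws.transitivity(model, beta), dtype=float)
    return _noisy_curve(beta, gamma, spec.noise_sigma, spec.seed, spec.units)


def generate_two_regime_transitivity(spec_a: SyntheticSpec,
                                     spec_b: SyntheticSpec,
                                     beta_c: float) -> TransitivityCurve:
    """Piecewise-linear transitivity curve with a crossover at beta_c.

    Both specs must carry AM laws whose gamma lines intersect at ``beta_c``;
    the resulting curve is exactly piecewise linear (before noise), the
    cleanest stage at which a crossover temperature manifests.
    """
    if spec_a.law != "am" or spec_b.law != "am":
        raise InvalidSpecError("two-regime construction requires AM laws")
    model_a = spec_a.model()
    model_b = spec_b.model()
    gam_a = 1.0 / model_a.eps_act - model_a.d * beta_c
    gam_b = 1.0 / model_b.eps_act - model_b.d * beta_c
    if abs(gam_a - gam_b) > 1e-8 * max(abs(gam_a), abs(gam_b), 1e-300):
        raise InvalidSpecError("transitivity lines do not intersect at beta_c")
    beta_a = spec_a.beta_grid()
    beta_b = spec_b.beta_grid()
    beta = np.concatenate([beta_a[beta_a <= beta_c], beta_b[beta_b > beta_c]])
    if beta.size < 3 or np.any(np.diff(beta) <= 0):
        raise InvalidSpecError("segment grids do not form an increasing beta grid")
    gamma = np.where(beta <= beta_c,
                     1.0 / model_a.eps_act - model_a.d * beta,
                     1.0 / model_b.eps_act - model_b.d * beta)
    return _noisy_curve(beta, gamma, spec_a.noise_sigma, spec_a.seed,
                        spec_a.units)
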