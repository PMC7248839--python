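"""Estimation of rate-law parameters from (T, k) data in both planes.

The workflow mirrors how non-Arrhenius kinetic data are analysed in
practice: fit candidate laws to ln k versus beta (the Arrhenius plane),
or transform the data to the transitivity plane — gamma(beta) = 1/Ea(beta)
with Ea estimated by numerical differentiation of ln k — where the deformed
(AM) law is a straight line, the Arrhenius law a constant and the VFT law a
parabola-rooted power law.  The universality exponent zeta of the
generalized transitivity law gamma = (1/eps)*(1-beta/beta_dagger)^zeta is
selected by profiling over a grid and comparing small-sample-corrected
information criteria; crossovers between two linear (AM) regimes are found
by exhaustive breakpoint search.

All objective functions act on ln k: rate data span orders of magnitude,
and multiplicative noise on k is additive there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares
from scipy.special import gammaincc

from . import laws
from .errors import (
    FitFailureError,
    InputError,
    NotApplicableError,
)
from .units import UnitSystem

logger = logging.getLogger(__name__)

__all__ = [
    "RateDataset",
    "TransitivityCurve",
    "FitResult",
    "small_sample_aic",
    "predict_log_rate",
    "fit_arrhenius_plane",
    "empirical_transitivity",
    "fit_transitivity_plane",
    "detect_crossover",
    "classify_behavior",
]

_LS_OPTS = dict(method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class RateDataset:
    """Ordered (beta, k) observations with unit metadata.

    ``beta`` must be strictly increasing and all rates positive; at least
    three points are required for any fit.
    """

    beta: np.ndarray
    k: np.ndarray
    units: UnitSystem = field(default_factory=UnitSystem)
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.beta.ndim != 1 or self.beta.shape != self.k.shape:
            raise InputError("beta and k must be 1-D arrays of equal length")
        if self.beta.size < 3:
            raise InputError("at least 3 (beta, k) points are required")
        if np.any(np.diff(self.beta) <= 0):
            raise InputError("beta values must be strictly increasing")
        if np.any(self.k <= 0) or not np.all(np.isfinite(self.k)):
            raise InputError("all rate constants must be positive and finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.beta.shape or np.any(self.weights <= 0):
                raise InputError("weights must be positive and match beta")

    @classmethod
    def from_temperature(cls, temperature, k, units: UnitSystem | None = None,
                         weights=None) -> "RateDataset":
        """Build from temperatures in kelvin; points are sorted by beta."""
        units = units or UnitSystem()
        beta = np.asarray(units.beta(np.asarray(temperature, dtype=float)))
        order = np.argsort(beta)
        k = np.asarray(k, dtype=float)[order]
        w = None if weights is None else np.asarray(weights, dtype=float)[order]
        return cls(beta=beta[order], k=k, units=units, weights=w)

    @property
    def n(self) -> int:
        return self.beta.size

    @property
    def log_k(self) -> np.ndarray:
        return np.log(self.k)

    @property
    def temperature(self) -> np.ndarray:
        return np.asarray(self.units.temperature(self.beta))


@dataclass
class TransitivityCurve:
    """(beta, gamma) pairs with the underlying Ea estimates and a validity mask.

    ``gamma * ea == 1`` pointwise wherever ``valid`` is True; points whose
    |Ea| fell below the masking tolerance carry gamma = NaN.
    """

    beta: np.ndarray
    ea: np.ndarray
    gamma: np.ndarray
    valid: np.ndarray
    method: str
    window: Optional[int] = None
    units: UnitSystem = field(default_factory=UnitSystem)

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    @classmethod
    def from_model(cls, model, beta, units: UnitSystem | None = None) -> "TransitivityCurve":
        """Exact curve evaluated from a closed-form rate-law model."""
        beta = np.asarray(beta, dtype=float)
        ea = np.asarray(laws.activation_energy(model, beta), dtype=float)
        valid = np.abs(ea) > 0
        gamma = np.full_like(ea, np.nan)
        gamma[valid] = 1.0 / ea[valid]
        return cls(beta=beta, ea=ea, gamma=gamma, valid=valid,
                   method="closed-form", units=units or UnitSystem())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "T_K": np.asarray(self.units.temperature(self.beta)),
                "Ea": self.ea,
                "gamma": self.gamma,
                "valid": self.valid,
            }
        )


@dataclass
class FitResult:
    """Converged fit: parameters, uncertainties and model-selection metadata."""

    law: str
    params: dict
    stderr: dict
    rss: float
    n_obs: int
    n_params: int
    aicc: float
    zeta: Optional[float] = None
    breakpoint: Optional[dict] = None
    profile: Optional[list] = None
    config: dict = field(default_factory=dict)


def small_sample_aic(rss: float, n: int, p: int, *, floor: float = 0.0) -> float:
    """AICc on Gaussian ln-k (or gamma) residuals: n*ln(RSS/n) + 2p + corr.

    ``floor`` guards the degenerate noiseless case where RSS underflows the
    numerical resolution of the residuals: all models below the floor are
    treated as equally perfect so parameter count decides.
    """
    if n <= 0:
        raise InputError("n must be positive")
    rss_eff = max(rss, floor, 1e-300)
    val = n * np.log(rss_eff / n) + 2.0 * p
    if n - p - 1 > 0:
        val += 2.0 * p * (p + 1) / (n - p - 1)
    else:
        val = np.inf
    return float(val)


# ---------------------------------------------------------------------------
# log-rate predictors (shared by fitting, reports and invariants)
# ---------------------------------------------------------------------------


def _am_log_rate(ln_a, eps, d, beta):
    """ln k of the deformed law, smooth through d = 0 and outside the domain.

    Outside 1 - d*eps*beta > 0 the log is clamped so optimisation residuals
    stay finite while being strongly repelled from the invalid region.
    """
    x = eps * beta
    if abs(d) < 1e-9:
        dx = d * x
        return ln_a - x * (1.0 + dx / 2.0 + dx**2 / 3.0 + dx**3 / 4.0)
    u = 1.0 - d * x
    out = ln_a + np.log1p(np.maximum(-d * x, 1e-12 - 1.0)) / d
    # linear ramp outside the domain keeps the optimiser informed
    out = out - np.where(u < 1e-12, (1e-12 - u) * 1e6, 0.0)
    return out


def _fg_log_rate(ln_a, eps, s, beta):
    x = np.clip(eps, 0.0, None) * beta
    return ln_a + np.log(np.clip(gammaincc(s, x), 1e-300, None))


def predict_log_rate(law: str, params: dict, beta) -> np.ndarray:
    """ln k at ``beta`` from a law tag and its fitted parameter mapping."""
    beta = np.asarray(beta, dtype=float)
    ln_a = np.log(params["A"])
    eps = params["eps_act"]
    if law == "arrhenius":
        return ln_a - eps * beta
    if law == "am":
        return _am_log_rate(ln_a, eps, params["d"], beta)
    if law == "vft":
        bd = params["beta_dagger"]
        return ln_a - eps * beta / (1.0 - beta / bd)
    if law == "fg":
        return _fg_log_rate(ln_a, eps, params["s"], beta)
    raise InputError(f"unknown law tag {law!r}")


# ---------------------------------------------------------------------------
# Arrhenius-plane fitting
# ---------------------------------------------------------------------------


def _line_fit(x, y, w=None):
    """Weighted straight line y = a + b*x; returns (a, b, rss, cov)."""
    w = np.ones_like(x) if w is None else w
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    resid = (np.column_stack([np.ones_like(x), x]) @ coef - y) * sw
    rss = float(resid @ resid)
    dof = x.size - 2
    if dof > 0:
        cov = rss / dof * np.linalg.inv(X.T @ X)
    else:
        cov = np.full((2, 2), np.nan)
    return coef[0], coef[1], rss, cov


def _stderr_from_jac(jac, rss, n, p):
    dof = n - p
    if dof <= 0:
        return np.full(jac.shape[1], np.nan)
    try:
        cov = rss / dof * np.linalg.inv(jac.T @ jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


def _multistart_ls(residual, starts, bounds=(-np.inf, np.inf)):
    best = None
    diagnostics = []
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=bounds, **_LS_OPTS)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not sol.success:
            diagnostics.append(f"start {x0}: {sol.message}")
            continue
        if best is None or sol.cost < best.cost - 1e-15 * (1 + abs(best.cost)):
            best = sol
    if best is None:
        raise FitFailureError("no optimisation start converged", diagnostics)
    return best


def fit_arrhenius_plane(data: RateDataset, law: str = "arrhenius",
                        init: dict | None = None, *, s_max: int = 30,
                        n_random_starts: int = 0, rng=None) -> FitResult:
    """Least-squares fit of a rate law to ln k versus beta.

    Initialisation starts from the ordinary Arrhenius line; the deformation
    parameter d is multi-started at {-0.1, -0.01, 0, 0.01, 0.1} and the VFT
    divergence at multiples of the largest observed beta.  A seedable
    stochastic-restart option (``n_random_starts``) supplements the
    deterministic starts for hard problems.
    """
    b = data.beta
    lnk = data.log_k
    w = np.ones_like(b) if data.weights is None else data.weights
    sw = np.sqrt(w)
    n = data.n

    ln_a0, slope, rss_line, cov_line = _line_fit(b, lnk, w)
    eps0 = -slope
    init = dict(init or {})
    if "A" in init:
        ln_a0 = np.log(init["A"])
    eps0 = init.get("eps_act", eps0)
    rng = np.random.default_rng(rng)

    if law == "arrhenius":
        params = {"A": float(np.exp(ln_a0)), "eps_act": float(eps0)}
        se = np.sqrt(np.clip(np.diag(cov_line), 0.0, None))
        stderr = {"A": float(params["A"] * se[0]), "eps_act": float(se[1])}
        return FitResult(
            law=law, params=params, stderr=stderr, rss=rss_line, n_obs=n,
            n_params=2, aicc=small_sample_aic(rss_line, n, 2),
        )

    if law == "am":
        def residual(t):
            return sw * (_am_log_rate(t[0], t[1], t[2], b) - lnk)

        d_starts = [init["d"]] if "d" in init else [0.0, 0.01, -0.01, 0.1, -0.1]
        starts = [np.array([ln_a0, eps0, d0]) for d0 in d_starts]
        for _ in range(n_random_starts):
            starts.append(np.array([ln_a0, eps0, rng.uniform(-0.3, 0.3)]))
        sol = _multistart_ls(residual, starts)
        ln_a, eps, d = sol.x
        rss = float(2 * sol.cost)
        se = _stderr_from_jac(sol.jac, rss, n, 3)
        params = {"A": float(np.exp(ln_a)), "eps_act": float(eps), "d": float(d)}
        stderr = {"A": float(params["A"] * se[0]), "eps_act": float(se[1]),
                  "d": float(se[2])}
        return FitResult(law=law, params=params, stderr=stderr, rss=rss,
                         n_obs=n, n_params=3, aicc=small_sample_aic(rss, n, 3))

    if law == "vft":
        b_max = b.max()
        lo = b_max * (1.0 + 1e-9)

        def residual(t):
            return sw * (t[0] - t[1] * b / (1.0 - b / t[2]) - lnk)

        bd_starts = [init["beta_dagger"]] if "beta_dagger" in init else \
            [1.5 * b_max, 1.2 * b_max, 2.5 * b_max, 5.0 * b_max]
        starts = [np.array([ln_a0, max(eps0, 1e-8), bd]) for bd in bd_starts]
        for _ in range(n_random_starts):
            starts.append(np.array([ln_a0, max(eps0, 1e-8),
                                    b_max * rng.uniform(1.05, 10.0)]))
        bounds = ([-np.inf, 1e-12, lo], [np.inf, np.inf, np.inf])
        sol = _multistart_ls(residual, starts, bounds)
        ln_a, eps, bd = sol.x
        rss = float(2 * sol.cost)
        se = _stderr_from_jac(sol.jac, rss, n, 3)
        params = {"A": float(np.exp(ln_a)), "eps_act": float(eps),
                  "beta_dagger": float(bd)}
        stderr = {"A": float(params["A"] * se[0]), "eps_act": float(se[1]),
                  "beta_dagger": float(se[2])}
        return FitResult(law=law, params=params, stderr=stderr, rss=rss,
                         n_obs=n, n_params=3, aicc=small_sample_aic(rss, n, 3))

    if law == "fg":
        best = None
        for s in range(1, s_max + 1):
            def residual(t, s=s):
                return sw * (_fg_log_rate(t[0], t[1], s, b) - lnk)

            starts = [np.array([ln_a0, max(abs(eps0), 1e-8)])]
            bounds = ([-np.inf, 1e-12], [np.inf, np.inf])
            try:
                sol = _multistart_ls(residual, starts, bounds)
            except FitFailureError:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[1]:
                best = (s, rss, sol)
        if best is None:
            raise FitFailureError("FG fit failed for every s", [])
        s, rss, sol = best
        se = _stderr_from_jac(sol.jac, rss, n, 3)
        params = {"A": float(np.exp(sol.x[0])), "eps_act": float(sol.x[1]),
                  "s": int(s)}
        stderr = {"A": float(params["A"] * se[0]), "eps_act": float(se[1]),
                  "s": float("nan")}
        return FitResult(law=law, params=params, stderr=stderr, rss=rss,
                         n_obs=n, n_params=3, aicc=small_sample_aic(rss, n, 3))

    raise InputError(f"unknown law {law!r}; expected arrhenius|am|vft|fg")


# ---------------------------------------------------------------------------
# empirical transitivity curve
# ---------------------------------------------------------------------------


def _local_poly_derivative(x, y, window: int, degree: int = 2):
    """Derivative from local least-squares polynomials (nonuniform grids).

    A Savitzky-Golay-type estimator: around each point, fit a polynomial of
    ``degree`` to the ``window`` nearest points and differentiate it there.
    """
    n = x.size
    half = window // 2
    dy = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        sel = slice(lo, lo + window)
        xs = x[sel] - x[i]
        V = np.vander(xs, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y[sel], rcond=None)
        dy[i] = coef[1]
    return dy


def empirical_transitivity(data: RateDataset, method: str = "spline", *,
                           ea_tol: float = 1e-10,
                           window: int | None = None) -> TransitivityCurve:
    """Transitivity curve gamma = 1/Ea from a dataset, Ea by differentiation.

    Methods: ``spline`` (default) — cubic smoothing spline of ln k versus
    beta with the smoothing level chosen by generalized cross-validation,
    differentiated analytically; ``central`` — second-order finite
    differences (one-sided at the ends), appropriate for dense low-noise
    data; ``window`` — local quadratic least squares over ``window`` points
    (default 7), robust for noisy data.  Points with |Ea| < ``ea_tol`` are
    masked rather than inverted.
    """
    if data.n < 5:
        raise InputError("derivative estimation requires at least 5 points")
    b, lnk = data.beta, data.log_k
    if method == "spline":
        spl = make_smoothing_spline(b, lnk)
        ea = -spl.derivative()(b)
        window = None
    elif method == "central":
        ea = -np.gradient(lnk, b, edge_order=2)
        window = None
    elif method == "window":
        window = window or 7
        if window % 2 == 0 or window < 3:
            raise InputError("window must be an odd integer >= 3")
        if data.n < window:
            raise InputError(f"need at least {window} points for window method")
        ea = -_local_poly_derivative(b, lnk, window)
    else:
        raise InputError(f"unknown derivative method {method!r}")
    ea = np.asarray(ea, dtype=float)
    valid = np.abs(ea) > ea_tol
    if not np.all(valid):
        logger.warning("masked %d transitivity points with |Ea| < %g",
                       int(np.sum(~valid)), ea_tol)
    gamma = np.full_like(ea, np.nan)
    gamma[valid] = 1.0 / ea[valid]
    return TransitivityCurve(beta=b.copy(), ea=ea, gamma=gamma, valid=valid,
                             method=method, window=window, units=data.units)


# ---------------------------------------------------------------------------
# transitivity-plane fitting and zeta selection
# ---------------------------------------------------------------------------


def _rss_floor(g: np.ndarray) -> float:
    # residuals below ~1e-10 of the gamma scale are numerically
    # indistinguishable from zero; ties then go to fewer parameters
    scale = max(float(np.max(np.abs(g))), 1e-30)
    return g.size * (1e-10 * scale) ** 2


def _fit_zeta_fixed(b, g, zeta):
    """LS fit of gamma = g0*(1-beta/beta_dagger)^zeta at fixed zeta.

    Returns (params, stderr, rss, p).  zeta = 0 degenerates to the constant
    gamma (pure Arrhenius) model with a single parameter.
    """
    n = b.size
    if zeta == 0:
        g0 = float(np.mean(g))
        rss = float(np.sum((g - g0) ** 2))
        se = np.sqrt(rss / (n - 1) / n) if n > 1 else np.nan
        eps = 1.0 / g0 if g0 != 0 else np.inf
        params = {"eps_act": eps, "gamma0": g0, "beta_dagger": np.inf}
        stderr = {"eps_act": abs(se / g0**2) if g0 != 0 else np.nan,
                  "gamma0": float(se), "beta_dagger": np.nan}
        return params, stderr, rss, 1

    b_max = b.max()
    lo = b_max * (1.0 + 1e-9)
    # linearised start: gamma^(1/zeta) is a straight line hitting 0 at beta_dagger
    g0_init, bd_init = None, None
    pos = g > 0
    if np.count_nonzero(pos) >= 3:
        u = g[pos] ** (1.0 / zeta)
        c0, c1, _, _ = _line_fit(b[pos], u)
        if c1 < 0 and c0 > 0 and -c0 / c1 > lo:
            bd_init = -c0 / c1
            g0_init = c0**zeta
    if g0_init is None:
        g0_init = float(np.max(np.abs(g)))
        bd_init = 1.5 * b_max

    def residual(t):
        return t[0] * (1.0 - b / t[1]) ** zeta - g

    starts = [np.array([g0_init, bd_init]),
              np.array([g0_init, 1.5 * b_max]),
              np.array([g0_init, 3.0 * b_max])]
    bounds = ([-np.inf, lo], [np.inf, np.inf])
    sol = _multistart_ls(residual, starts, bounds)
    g0, bd = sol.x
    rss = float(2 * sol.cost)
    se = _stderr_from_jac(sol.jac, rss, n, 2)
    eps = 1.0 / g0 if g0 != 0 else np.inf
    params = {"eps_act": float(eps), "gamma0": float(g0),
              "beta_dagger": float(bd)}
    stderr = {"eps_act": float(abs(se[0] / g0**2)) if g0 != 0 else np.nan,
              "gamma0": float(se[0]), "beta_dagger": float(se[1])}
    if zeta == 1:
        params["d"] = float(g0 / bd)
        params["slope"] = float(-g0 / bd)
    return params, stderr, rss, 2


def fit_transitivity_plane(curve: TransitivityCurve,
                           zeta: float | None = None,
                           zeta_grid=None) -> FitResult:
    """Fit the generalized transitivity law, optionally selecting zeta.

    With ``zeta`` fixed, a nonlinear LS fit for (eps_act, beta_dagger).
    With ``zeta`` free, the exponent is profiled over a grid (default 0 to 4
    in steps of 0.05, always including the integer classes 0, 1, 2) and the
    winner chosen by AICc; exact ties go to fewer parameters, then to the
    smaller exponent.
    """
    b = curve.beta[curve.valid]
    g = curve.gamma[curve.valid]
    if b.size < 4:
        raise InputError("need at least 4 unmasked transitivity points")
    floor = _rss_floor(g)

    if zeta is not None:
        params, stderr, rss, p = _fit_zeta_fixed(b, g, float(zeta))
        return FitResult(law="zeta", params=params, stderr=stderr, rss=rss,
                         n_obs=b.size, n_params=p,
                         aicc=small_sample_aic(rss, b.size, p, floor=floor),
                         zeta=float(zeta))

    if zeta_grid is None:
        zeta_grid = np.round(np.arange(0.0, 4.0 + 1e-9, 0.05), 10)
    candidates = sorted(set(float(z) for z in zeta_grid) | {0.0, 1.0, 2.0})
    profile = []
    fits = {}
    for z in candidates:
        try:
            params, stderr, rss, p = _fit_zeta_fixed(b, g, z)
        except FitFailureError:
            continue
        aic = small_sample_aic(rss, b.size, p, floor=floor)
        profile.append({"zeta": z, "rss": rss, "aicc": aic, "n_params": p})
        fits[z] = (params, stderr, rss, p, aic)
    if not fits:
        raise FitFailureError("transitivity-plane fit failed at every zeta", [])
    best_aic = min(f[4] for f in fits.values())
    eligible = [z for z, f in fits.items() if f[4] <= best_aic + 1e-9]
    z_sel = min(eligible, key=lambda z: (fits[z][3], z))
    params, stderr, rss, p, aic = fits[z_sel]
    return FitResult(law="zeta", params=params, stderr=stderr, rss=rss,
                     n_obs=b.size, n_params=p, aicc=aic, zeta=float(z_sel),
                     profile=profile)


# ---------------------------------------------------------------------------
# crossover detection
# ---------------------------------------------------------------------------


def detect_crossover(curve: TransitivityCurve, *, min_points: int = 3,
                     aicc_margin: float = 2.0) -> FitResult:
    """Exhaustive breakpoint search for two linear (AM) transitivity regimes.

    Each interior grid point beta_c is tried as the joint of two
    independently fitted straight lines (the candidate point belongs to
    both segments, matching a gamma-continuous crossover); the candidate
    minimising the total RSS is compared with the single-line fit by AICc.
    The single-line model is preferred unless the two-regime model improves
    the criterion by at least ``aicc_margin`` *and* lowers the RSS.
    """
    b = curve.beta[curve.valid]
    g = curve.gamma[curve.valid]
    n = b.size
    if n < 7:
        raise InputError("breakpoint detection requires at least 7 unmasked points")
    floor = _rss_floor(g)

    a_s, slope_s, rss_single, cov_s = _line_fit(b, g)
    aic_single = small_sample_aic(rss_single, n, 2, floor=floor)

    best_i, best_rss, best_parts = None, np.inf, None
    for i in range(min_points - 1, n - min_points + 1):
        # left segment 0..i and right segment i..n-1 share the joint point
        aL, sL, rssL, _ = _line_fit(b[: i + 1], g[: i + 1])
        aR, sR, rssR, _ = _line_fit(b[i:], g[i:])
        total = rssL + rssR
        if best_i is None or total < best_rss - 1e-15 * (1 + best_rss):
            best_i, best_rss = i, total
            best_parts = (aL, sL, aR, sR)
    aic_break = small_sample_aic(best_rss, n, 5, floor=floor)

    select_break = (aic_single - aic_break >= aicc_margin) and \
        (best_rss <= rss_single)
    aL, sL, aR, sR = best_parts
    breakpoint_info = {
        "beta_c": float(b[best_i]),
        "T_c": float(curve.units.temperature(b[best_i])),
        "index": int(best_i),
        "left": {"eps_act": float(1.0 / aL) if aL != 0 else np.inf,
                 "d": float(-sL), "intercept": float(aL), "slope": float(sL)},
        "right": {"eps_act": float(1.0 / aR) if aR != 0 else np.inf,
                  "d": float(-sR), "intercept": float(aR), "slope": float(sR)},
        "rss_single": float(rss_single),
        "rss_break": float(best_rss),
        "aicc_single": float(aic_single),
        "aicc_break": float(aic_break),
        "selected": bool(select_break),
    }
    if select_break:
        return FitResult(
            law="am_two_regime",
            params={"beta_c": breakpoint_info["beta_c"],
                    "T_c": breakpoint_info["T_c"],
                    "left": breakpoint_info["left"],
                    "right": breakpoint_info["right"]},
            stderr={}, rss=float(best_rss), n_obs=n, n_params=5,
            aicc=aic_break, breakpoint=breakpoint_info,
        )
    se = np.sqrt(np.clip(np.diag(cov_s), 0.0, None))
    params = {"eps_act": float(1.0 / a_s) if a_s != 0 else np.inf,
              "d": float(-slope_s), "intercept": float(a_s),
              "slope": float(slope_s)}
    stderr = {"d": float(se[1]),
              "eps_act": float(se[0] / a_s**2) if a_s != 0 else np.nan}
    return FitResult(law="am", params=params, stderr=stderr,
                     rss=float(rss_single), n_obs=n, n_params=2,
                     aicc=aic_single, breakpoint=breakpoint_info)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_behavior(fit: FitResult, tol: float = 1e-3) -> str:
    """Classify an AM fit by the sign of the deformation parameter.

    Returns one of ``arrhenius`` (|d| within tolerance of zero),
    ``sub-arrhenius`` (d < 0, tunneling-like concavity), ``super-arrhenius``
    (d > 0 with a positive barrier) or ``anti-arrhenius`` (d > 0 with
    eps_act < 0).  When a standard error for d is available the tolerance
    is widened to two standard errors.
    """
    if "d" not in fit.params:
        raise NotApplicableError("classification requires a deformed-law fit")
    d = fit.params["d"]
    eps = fit.params.get("eps_act", np.nan)
    se = fit.stderr.get("d")
    threshold = tol
    if se is not None and np.isfinite(se):
        threshold = max(tol, 2.0 * se)
    if abs(d) <= threshold:
        return "arrhenius"
    if d > 0 and eps < 0:
        return "anti-arrhenius"
    if d > 0:
        return "super-arrhenius"
    return "sub-arrhenius"
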