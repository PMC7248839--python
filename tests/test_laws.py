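"""Closed-form rate laws: point values, limits, and analytic identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import transitivity as tr
from transitivity import laws
from transitivity.errors import (
    DomainError,
    InvalidParameterError,
    NoFiniteLimitError,
    NotApplicableError,
)

E = np.e


# ---------------------------------------------------------------------------
# point values
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "params, beta, expected",
    [
        (dict(A=1.0, eps_act=1.0), 0.0, 1.0),
        (dict(A=1.0, eps_act=1.0), 1.0, 1 / E),
        (dict(A=2.0, eps_act=0.0), 3.7, 2.0),  # barrierless limit
    ],
)
def test_arrhenius_values(params, beta, expected):
    assert tr.k_arrhenius(tr.ArrheniusParams(**params), beta) == pytest.approx(expected)


@pytest.mark.parametrize(
    "d, beta, expected",
    [
        (0.5, 1.0, 0.25),   # (1 - 0.5)^2
        (-1.0, 1.0, 0.5),   # (1 + 1)^-1
    ],
)
def test_am_values(d, beta, expected):
    p = tr.AMParams(A=1.0, eps_act=1.0, d=d)
    assert tr.k_am(p, beta) == pytest.approx(expected, rel=1e-14)


def test_am_small_d_matches_arrhenius():
    p = tr.AMParams(A=1.0, eps_act=1.0, d=1e-8)
    assert tr.k_am(p, 2.0) == pytest.approx(np.exp(-2.0), rel=1e-6)


def test_am_d_zero_is_exactly_arrhenius():
    p = tr.AMParams(A=3.0, eps_act=2.0, d=0.0)
    b = np.linspace(0, 4, 9)
    np.testing.assert_array_equal(
        tr.k_am(p, b), tr.k_arrhenius(tr.ArrheniusParams(A=3.0, eps_act=2.0), b))


def test_am_boundary_continuous_extension_and_strict_flag():
    p = tr.AMParams(A=1.0, eps_act=2.0, d=0.5)  # beta_dagger = 1
    assert tr.k_am(p, 1.0) == 0.0
    with pytest.raises(DomainError, match="beta_dagger"):
        tr.k_am(p, 1.0, strict_domain=True)
    with pytest.raises(DomainError):
        tr.k_am(p, 1.5)


def test_vft_values():
    p = tr.VFTParams(A=2.0, eps_act=1.0, beta_dagger=1.0)
    assert tr.k_vft(p, 0.0) == pytest.approx(2.0)
    p1 = tr.VFTParams(A=1.0, eps_act=1.0, beta_dagger=1.0)
    assert tr.k_vft(p1, 0.5) == pytest.approx(1 / E, rel=1e-12)
    b = np.linspace(0.0, 0.999, 200)
    assert np.all(np.diff(tr.k_vft(p1, b)) < 0)  # k -> 0 monotonically
    with pytest.raises(DomainError):
        tr.k_vft(p1, 1.0)


@pytest.mark.parametrize(
    "s, expected",
    [(2, 2 / E), (3, 2.5 / E)],
)
def test_fg_series_values(s, expected):
    p = tr.FGParams(A=1.0, eps_act=1.0, s=s)
    assert tr.k_fg_series(p, 1.0) == pytest.approx(expected, rel=1e-14)


def test_fg_s1_and_closed_form_reduce_to_arrhenius():
    p = tr.FGParams(A=1.5, eps_act=2.0, s=1)
    b = np.linspace(0, 5, 11)
    np.testing.assert_allclose(tr.k_fg_series(p, b), 1.5 * np.exp(-2.0 * b),
                               rtol=1e-14)
    np.testing.assert_allclose(tr.k_fg_closed(p, b), 1.5 * np.exp(-2.0 * b),
                               rtol=1e-13)


def test_fg_zero_coldness_gives_prefactor():
    for s in (1, 3, 10):
        p = tr.FGParams(A=7.0, eps_act=5.0, s=s)
        assert tr.k_fg_closed(p, 0.0) == pytest.approx(7.0)


def test_fg_series_equals_closed_form_broadly():
    # finite sum vs incomplete-gamma form across the full contract range
    x = np.linspace(0.0, 50.0, 26)
    for s in range(1, 31):
        p = tr.FGParams(A=1.0, eps_act=1.0, s=s)
        np.testing.assert_allclose(tr.k_fg_series(p, x), tr.k_fg_closed(p, x),
                                   rtol=1e-12, atol=0)


# ---------------------------------------------------------------------------
# activation energy and transitivity
# ---------------------------------------------------------------------------


def test_activation_energy_closed_forms():
    assert tr.activation_energy(tr.AMParams(1.0, 1.0, 0.5), 1.0) == pytest.approx(2.0)
    # FG: Ea = eps * x^{s-1} e^{-x} / Gamma(s, x); s=2, x=1 -> 0.5
    assert tr.activation_energy(tr.FGParams(1.0, 1.0, 2), 1.0) == pytest.approx(0.5, rel=1e-12)
    # Arrhenius reductions
    assert tr.activation_energy(tr.AMParams(1.0, 3.0, 0.0), 0.7) == 3.0
    assert tr.activation_energy(tr.FGParams(1.0, 3.0, 1), 0.7) == pytest.approx(3.0)


@pytest.mark.parametrize(
    "model, betas",
    [
        (tr.ArrheniusParams(A=1e13, eps_act=40.0), np.linspace(0.05, 0.45, 5)),
        (tr.AMParams(A=1e13, eps_act=40.0, d=0.05), np.linspace(0.05, 0.45, 5)),
        (tr.AMParams(A=1.0, eps_act=1.0, d=-0.3), np.linspace(0.5, 5.0, 5)),
        (tr.VFTParams(A=1e13, eps_act=10.0, beta_dagger=0.8), np.linspace(0.05, 0.6, 5)),
        (tr.FGParams(A=1.0, eps_act=4.0, s=5), np.linspace(0.2, 3.0, 5)),
        (tr.ZetaParams(A=1.0, eps_act=2.0, beta_dagger=1.0, zeta=1.5),
         np.linspace(0.1, 0.8, 5)),
    ],
    ids=["arrhenius", "am-super", "am-sub", "vft", "fg", "zeta1.5"],
)
def test_activation_energy_matches_numerical_derivative(model, betas):
    closed = tr.activation_energy(model, betas)
    numeric = tr.numerical_activation_energy(lambda b: laws.log_rate(model, b), betas)
    np.testing.assert_allclose(closed, numeric, rtol=1e-6)


def test_transitivity_is_reciprocal_ea_and_linear_for_am():
    assert tr.transitivity(tr.AMParams(1.0, 2.0, 0.1), 0.0) == pytest.approx(0.5)
    assert tr.transitivity(tr.AMParams(1.0, 1.0, 0.5), 1.0) == pytest.approx(0.5)
    assert tr.transitivity(tr.FGParams(1.0, 1.0, 2), 1.0) == pytest.approx(2.0, rel=1e-12)
    # noiseless line fit through gamma recovers slope -d, intercept 1/eps
    m = tr.AMParams(A=1e13, eps_act=40.0, d=0.05)
    b = np.linspace(0.05, 0.45, 30)
    slope, intercept = np.polyfit(b, tr.transitivity(m, b), 1)
    assert slope == pytest.approx(-0.05, abs=1e-10)
    assert intercept == pytest.approx(1 / 40.0, abs=1e-10)


# ---------------------------------------------------------------------------
# generalized transitivity law
# ---------------------------------------------------------------------------


def test_zeta_classes_reproduce_their_laws():
    b = np.linspace(0.0, 0.45, 20)
    z0 = tr.ZetaParams(A=1e13, eps_act=40.0, beta_dagger=1.0, zeta=0.0)
    np.testing.assert_allclose(
        tr.rate_from_transitivity(z0, b),
        tr.k_arrhenius(tr.ArrheniusParams(A=1e13, eps_act=40.0), b), rtol=1e-8)
    am = tr.AMParams(A=1e13, eps_act=40.0, d=0.05)
    z1 = tr.ZetaParams(A=1e13, eps_act=40.0, beta_dagger=am.beta_dagger, zeta=1.0)
    np.testing.assert_allclose(tr.rate_from_transitivity(z1, b),
                               tr.k_am(am, b), rtol=1e-8)
    vft = tr.VFTParams(A=1e13, eps_act=10.0, beta_dagger=0.8)
    z2 = tr.ZetaParams(A=1e13, eps_act=10.0, beta_dagger=0.8, zeta=2.0)
    np.testing.assert_allclose(tr.rate_from_transitivity(z2, b),
                               tr.k_vft(vft, b), rtol=1e-8)


def test_noninteger_zeta_matches_brute_force_quadrature():
    z = tr.ZetaParams(A=1.0, eps_act=1.0, beta_dagger=2.0, zeta=1.5)
    beta = 1.0
    # high-resolution trapezoid oracle for int_0^beta (1-u/bd)^(-zeta) du
    u = np.linspace(0.0, beta, 200001)
    integral = np.trapezoid((1 - u / 2.0) ** -1.5, u)
    assert tr.rate_from_transitivity(z, beta) == pytest.approx(
        np.exp(-integral), rel=1e-6)


def test_zeta_domain_error():
    z = tr.ZetaParams(A=1.0, eps_act=1.0, beta_dagger=1.0, zeta=2.0)
    with pytest.raises(DomainError):
        tr.rate_from_transitivity(z, 1.0)


# ---------------------------------------------------------------------------
# expansion, tunneling, thermal limits, Wigner asymptote
# ---------------------------------------------------------------------------


def test_am_expansion_values_and_order():
    p0 = tr.AMParams(A=2.0, eps_act=1.0, d=0.0)
    b = np.linspace(0, 0.9, 7)
    np.testing.assert_allclose(tr.am_expansion(p0, b), 2.0 * np.exp(-b), rtol=1e-15)
    p = tr.AMParams(A=1.0, eps_act=1.0, d=0.1)
    assert tr.am_expansion(p, 0.1) == pytest.approx(tr.k_am(p, 0.1), rel=1e-7)
    # higher order is strictly more accurate
    p5 = tr.AMParams(A=1.0, eps_act=1.0, d=0.5)
    e2 = abs(tr.am_expansion(p5, 0.2, order=2) - tr.k_am(p5, 0.2))
    e4 = abs(tr.am_expansion(p5, 0.2, order=4) - tr.k_am(p5, 0.2))
    assert e4 < e2


def test_am_expansion_error_scales_as_fifth_power():
    # truncation error ~ x^5: log-log slope 5 +- 0.2 on a resolvable range
    p = tr.AMParams(A=1.0, eps_act=1.0, d=0.5)
    x = np.logspace(-2, -1, 20)
    err = np.abs(tr.am_expansion(p, x, order=4) - tr.k_am(p, x))
    slope = np.polyfit(np.log(x), np.log(err), 1)[0]
    assert slope == pytest.approx(5.0, abs=0.2)
    # halving beta cuts the error about 2^5-fold
    ratio = (abs(tr.am_expansion(p, 0.1) - tr.k_am(p, 0.1))
             / abs(tr.am_expansion(p, 0.05) - tr.k_am(p, 0.05)))
    assert ratio == pytest.approx(32.0, rel=0.1)


@pytest.mark.parametrize(
    "h_nu_over_eps, expected",
    [(2.0, -1.0 / 3.0), (1.0, -1.0 / 12.0), (0.0, 0.0)],
)
def test_tunneling_deformation(h_nu_over_eps, expected):
    # express h*nu directly through the ratio to the barrier
    assert tr.d_from_tunneling(h_nu_over_eps, 1.0, h=1.0) == pytest.approx(expected)


def test_tunneling_requires_barrier():
    with pytest.raises(InvalidParameterError):
        tr.d_from_tunneling(1.0, 0.0, h=1.0)


def test_thermal_limits():
    lims = tr.thermal_limits(tr.AMParams(A=1.0, eps_act=10.0, d=0.1))
    assert lims.eps_dagger == pytest.approx(1.0)
    assert lims.beta_dagger == pytest.approx(1.0)
    assert lims.T_dagger == pytest.approx(1.0 / 8.3144626e-3)
    # unit-conversion cross-check in a second system
    u = tr.UnitSystem(energy_unit="kcal/mol")
    lims2 = tr.thermal_limits(tr.AMParams(A=1.0, eps_act=40.0, d=0.05), u)
    assert lims2.T_dagger == pytest.approx(2.0 / 1.9872043e-3)
    # the rate law vanishes at the boundary
    assert tr.k_am(tr.AMParams(1.0, 10.0, 0.1), lims.beta_dagger) == 0.0
    with pytest.raises(NoFiniteLimitError):
        tr.thermal_limits(tr.AMParams(A=1.0, eps_act=10.0, d=-0.1))


def test_wigner_asymptote():
    p = tr.AMParams(A=1.0, eps_act=1.0, d=-1.0)
    assert tr.wigner_asymptote_residual(p, 1.0) == pytest.approx(0.5)
    assert tr.wigner_asymptote_residual(p, 1e6) == pytest.approx(1.0, abs=1e-5)
    # monotone approach on a geometric grid
    ph = tr.AMParams(A=1.0, eps_act=1.0, d=-0.5)
    resid = tr.wigner_asymptote_residual(ph, 2.0 ** np.arange(0, 12))
    assert np.all(np.diff(np.abs(resid - 1.0)) < 0)
    with pytest.raises(NotApplicableError):
        tr.wigner_asymptote_residual(tr.AMParams(1.0, 1.0, 0.1), 1.0)


# ---------------------------------------------------------------------------
# invariants (property-based)
# ---------------------------------------------------------------------------


def test_arrhenius_reduction_invariant():
    eps = 2.5
    p = tr.AMParams(A=1.0, eps_act=eps, d=1e-10)
    b = np.linspace(0.0, 5.0 / eps, 50)
    diff = np.abs(np.log(tr.k_am(p, b)) + eps * b)
    assert np.max(diff) < 1e-8


@settings(derandomize=True, max_examples=60)
@given(
    st.sampled_from(["arrhenius", "am", "vft", "fg"]),
    st.floats(min_value=0.5, max_value=50.0),
)
def test_monotone_decreasing_in_beta(law, eps):
    # positive barrier: k never increases with coldness on the valid domain
    if law == "arrhenius":
        model = tr.ArrheniusParams(A=1.0, eps_act=eps)
        b = np.linspace(0, 2.0 / eps, 40)
    elif law == "am":
        model = tr.AMParams(A=1.0, eps_act=eps, d=0.1)
        b = np.linspace(0, 0.99 * model.beta_dagger, 40)
    elif law == "vft":
        model = tr.VFTParams(A=1.0, eps_act=eps, beta_dagger=1.0)
        b = np.linspace(0, 0.95, 40)
    else:
        model = tr.FGParams(A=1.0, eps_act=eps, s=4)
        b = np.linspace(0, 5.0 / eps, 40)
    k = tr.rate(model, b)
    assert np.all(np.diff(k) <= 1e-12 * k[:-1])


def test_invalid_prefactor_rejected():
    with pytest.raises(InvalidParameterError):
        tr.ArrheniusParams(A=0.0, eps_act=1.0)
    with pytest.raises(InvalidParameterError):
        tr.FGParams(A=1.0, eps_act=1.0, s=0)
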