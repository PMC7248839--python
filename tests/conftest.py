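"""Shared fixtures: canonical study conditions used across the suite.

The reference scenarios are a single super-Arrhenius process with a 40
kJ/mol barrier observed between 250 and 400 K, and a two-regime crossover
process (transitivity slopes -0.02 and -0.10) observed between 200 and
400 K on a 41-point coldness grid with the crossover at the midpoint.
"""

import numpy as np
import pytest

import transitivity as tr


@pytest.fixture(scope="session")
def units():
    return tr.UnitSystem()  # kJ/mol, kB = 0.0083144626 kJ/mol/K


@pytest.fixture(scope="session")
def am_reference():
    """AM study conditions: A=1e13, eps=40 kJ/mol, d=0.05, 30 pts, 250-400 K."""
    return dict(A=1e13, eps_act=40.0, d=0.05)


@pytest.fixture
def am_spec(am_reference):
    return tr.SyntheticSpec(law="am", params=am_reference,
                            t_min=250.0, t_max=400.0, n=30)


@pytest.fixture(scope="session")
def crossover_setup(units):
    """Two-regime layout: slopes -0.02/-0.10, 200-400 K, 41-point beta grid."""
    b_lo, b_hi = units.beta(400.0), units.beta(200.0)
    grid = np.linspace(b_lo, b_hi, 41)
    i_c = 20
    beta_c = grid[i_c]
    pa = tr.AMParams(A=1e13, eps_act=35.0, d=0.02)
    pb = tr.matched_am_segment(pa, beta_c, 0.10)

    def make_specs(sigma=0.0, seed=0):
        spec_a = tr.SyntheticSpec(
            law="am", params=dict(A=pa.A, eps_act=pa.eps_act, d=pa.d),
            t_min=units.temperature(beta_c), t_max=400.0, n=i_c + 1,
            grid="beta", noise_sigma=sigma, seed=seed, units=units)
        spec_b = tr.SyntheticSpec(
            law="am", params=dict(A=pb.A, eps_act=pb.eps_act, d=pb.d),
            t_min=200.0, t_max=units.temperature(grid[i_c + 1]), n=40 - i_c,
            grid="beta", noise_sigma=sigma, seed=seed, units=units)
        return spec_a, spec_b

    return dict(grid=grid, i_c=i_c, beta_c=beta_c, params_a=pa, params_b=pb,
                make_specs=make_specs)
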