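"""Unit tests of the vector-field building blocks and its symmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tadcpg as tc
from tadcpg import model
from tadcpg.params import RateCoeffs


# ----------------------------------------------------------------------
# scalar terms


@pytest.mark.parametrize("v,coeffs,expected", [
    (0.0, (1, 0, 1, 0, 1), 0.5),            # 1/(1+exp(0))
    (-3.0, (2, 0, 0.7, 3, 5), 2.0 / 1.7),   # v=-D -> exp(0)=1
    (0.0, (2, 0.1, 0, 0, 5), 2.0),          # C=0, denominator exp(0)=1
])
def test_rate_fn_closed_form(v, coeffs, expected):
    assert tc.rate_fn(v, coeffs) == pytest.approx(expected, rel=1e-12)


def test_rate_fn_overflow_saturates():
    # huge positive exponent: denominator -> inf, rate -> 0
    assert tc.rate_fn(1e5, (1.0, 0.0, 1.0, 0.0, 1.0)) == 0.0


def test_rate_fn_rejects_zero_E():
    with pytest.raises(ValueError):
        tc.rate_fn(0.0, (1, 0, 1, 0, 0))


@settings(max_examples=50, deadline=None)
@given(v=st.floats(-120, 60), x=st.floats(0, 1))
def test_gating_deriv_pushes_into_unit_interval(v, x):
    coeffs = RateCoeffs(alpha=(1.2, 0, 1, 10, -8), beta=(0.9, 0, 1, 30, 6))
    a = tc.rate_fn(v, coeffs.alpha)
    b = tc.rate_fn(v, coeffs.beta)
    d = tc.gating_deriv(x, v, coeffs)
    assert np.isfinite(d)
    if x == 0.0:
        assert d == pytest.approx(a)
    if x == 1.0:
        assert d == pytest.approx(-b)


def test_gating_fixed_point_is_alpha_over_sum():
    coeffs = RateCoeffs(alpha=(1.2, 0, 1, 10, -8), beta=(0.9, 0, 1, 30, 6))
    v = -40.0
    a, b = tc.rate_fn(v, coeffs.alpha), tc.rate_fn(v, coeffs.beta)
    assert tc.gating_deriv(a / (a + b), v, coeffs) == pytest.approx(0.0, abs=1e-15)


def test_mg_block_shape():
    assert tc.mg_block(0.0) == pytest.approx(1.0 / 1.05)
    assert tc.mg_block(500.0) == pytest.approx(1.0, abs=1e-6)
    assert tc.mg_block(-500.0) == pytest.approx(0.0, abs=1e-6)
    v = np.linspace(-100, 50, 200)
    vals = np.array([tc.mg_block(x) for x in v])
    assert np.all(np.diff(vals) > 0)
    assert np.all((vals > 0) & (vals < 1))


def test_transmitter_conc_midpoint_and_saturation(params):
    ampa = params.synapses["ampa"]
    assert tc.transmitter_conc(ampa.vbar, ampa) == pytest.approx(ampa.T / 2)
    assert tc.transmitter_conc(1e4, ampa) == pytest.approx(ampa.T)
    assert tc.transmitter_conc(-1e4, ampa) == pytest.approx(0.0, abs=1e-12)
    # Table values: AMPA saturates at 4 with midpoint +10 mV
    assert tc.transmitter_conc(10.0, ampa) == pytest.approx(2.0)


def test_synapse_deriv_fixed_point_and_decay(params):
    s = params.synapses["glycine"]
    v_pre, tau = 20.0, s.tau_c
    g = tc.transmitter_conc(v_pre, s)
    y_star = g * tau / (1 + g * tau)
    assert tc.synapse_deriv(y_star, v_pre, tau, s) == pytest.approx(0.0, abs=1e-14)
    # silent presynapse: pure decay
    assert tc.synapse_deriv(0.5, -90.0, tau, s) == pytest.approx(-0.5 / tau,
                                                                 rel=1e-6)


def test_synaptic_current_reversal_and_sign(params):
    gly = params.synapses["glycine"]
    assert tc.synaptic_current(gly.e, 0.2, 0.6, gly, 10.0) == 0.0
    assert tc.synaptic_current(-50.0, 0.3, 0.3, gly, 10.0) == 0.0
    # open glycine synapse above its reversal is hyperpolarizing
    assert tc.synaptic_current(-50.0, 0.1, 0.5, gly, 10.0) < 0
    nmda = params.synapses["nmda"]
    raw = nmda.e - (-30.0)
    i = tc.synaptic_current(-30.0, 0.0, 1.0, nmda, 1.0)
    assert i == pytest.approx(raw * tc.mg_block(-30.0))


# ----------------------------------------------------------------------
# intrinsic currents


def test_ionic_currents_reversal_zeros(params):
    gating = {"m": 0.5, "h": 0.5, "f": 0.5, "l": 0.5, "r": 0.5}
    d = params.dIN
    ca = params.calcium
    assert tc.ionic_currents(d.e_lk, gating, d, ca)["i_lk"] == 0.0
    assert tc.ionic_currents(d.e_na, gating, d, ca)["i_na"] == 0.0
    assert tc.ionic_currents(d.e_kf, gating, d, ca)["i_kf"] == 0.0
    assert tc.ionic_currents(d.e_ks, gating, d, ca)["i_ks"] == 0.0


def test_leak_current_value_below_rest(params):
    # 10 mV below the leak reversal with g_lk = 1.4 nS -> +14 pA
    gating = {"m": 0, "h": 0, "f": 0, "l": 0, "r": 0}
    cur = tc.ionic_currents(params.dIN.e_lk - 10.0, gating, params.dIN,
                            params.calcium)
    assert cur["i_lk"] == pytest.approx(params.dIN.g_lk * 10.0)


def test_calcium_gate_closed_means_no_current(params):
    gating = {"m": 0.5, "h": 0.5, "f": 0.5, "l": 0.5, "r": 0.0}
    cur = tc.ionic_currents(-30.0, gating, params.dIN, params.calcium)
    assert cur["i_ca"] == 0.0


def test_cin_has_no_calcium_current(params):
    gating = {"m": 0.5, "h": 0.5, "f": 0.5, "l": 0.5}
    cur = tc.ionic_currents(-30.0, gating, params.cIN)
    assert cur["i_ca"] == 0.0


def test_ghk_continuity_at_zero_voltage(params):
    ca = params.calcium
    r = 0.3
    limit = 2 * ca.p_ca * ca.faraday * (ca.ca_out - ca.ca_in) * r * r
    below = tc.ghk_current(-1e-6, r, ca)
    above = tc.ghk_current(+1e-6, r, ca)
    assert below == pytest.approx(limit, rel=1e-4)
    assert above == pytest.approx(limit, rel=1e-4)
    assert min(below, above) <= limit <= max(below, above)


def test_ghk_equal_concentrations_collapse(params):
    # with ca_in = ca_out = c the bracket collapses to mu*c
    import copy
    ca = copy.deepcopy(params.calcium)
    ca.ca_in = ca.ca_out = 1e-6
    v = -40.0
    mu = 2 * ca.faraday * v * 1e-3 / (ca.gas_constant * ca.temperature_K)
    expected = -2 * ca.p_ca * ca.faraday * mu * 1e-6
    assert tc.ghk_current(v, 1.0, ca) == pytest.approx(expected, rel=1e-9)


def test_ghk_depolarizing_at_rest(params):
    # calcium influx (ca_out > ca_in) depolarizes at physiological voltages
    assert tc.ghk_current(-50.0, 0.5, params.calcium) > 0


# ----------------------------------------------------------------------
# assembled field and symmetry


def test_vector_field_dimension(params, rest):
    dy = tc.network_vector_field(0.0, rest, params)
    assert dy.shape == (34,)


def test_swap_sides_is_involution_and_block_exchange(rng):
    y = rng.uniform(0, 1, 34)
    assert np.array_equal(tc.swap_sides(tc.swap_sides(y)), y)
    e0 = np.zeros(34)
    e0[0] = 1.0
    assert tc.swap_sides(e0)[17] == 1.0
    sym = np.concatenate([y[:17], y[:17]])
    assert np.array_equal(tc.swap_sides(sym), sym)


def test_field_is_equivariant_under_side_swap(params, rng):
    P = tc.pack_params(params)
    worst = 0.0
    for _ in range(100):
        y = np.empty(34)
        for side in (0, 17):
            y[side] = rng.uniform(-80, 40)         # dIN v
            y[side + 6] = rng.uniform(-80, 40)     # cIN v
            y[side + 1:side + 6] = rng.uniform(0, 1, 5)
            y[side + 7:side + 11] = rng.uniform(0, 1, 4)
            y[side + 11:side + 17] = rng.uniform(0, 1, 6)
        lhs = tc.swap_sides(tc.network_vector_field(0.0, y, P))
        rhs = tc.network_vector_field(0.0, tc.swap_sides(y), P)
        worst = max(worst, np.max(np.abs(lhs - rhs)))
    assert worst == 0.0


def test_symmetry_broken_field_is_not_equivariant(params, rng):
    from tadcpg.experiments import symmetry_breaking_perturbation
    q = symmetry_breaking_perturbation(params, sd=0.1, seed=7)
    P = tc.pack_params(q)
    y = rng.uniform(0.1, 0.9, 34)
    y[[0, 6, 17, 23]] = [-50.0, -60.0, -45.0, -55.0]
    lhs = tc.swap_sides(tc.network_vector_field(0.0, y, P))
    rhs = tc.network_vector_field(0.0, tc.swap_sides(y), P)
    assert np.max(np.abs(lhs - rhs)) > 1e-6


def test_half_system_dimension_and_embedding(params, rest):
    dy_half = tc.half_system_vector_field(0.0, rest[:17], params)
    assert dy_half.shape == (17,)
    # the resting state restricted to one block is a half-system fixed point
    assert np.max(np.abs(dy_half)) < 1e-7
    full = tc.network_vector_field(0.0, tc.embed_half_state(rest[:17]), params)
    assert np.allclose(np.concatenate([dy_half, dy_half]), full, atol=1e-12)


def test_half_system_refuses_broken_symmetry(params):
    from tadcpg.experiments import symmetry_breaking_perturbation
    q = symmetry_breaking_perturbation(params, sd=0.1, seed=3)
    with pytest.raises(ValueError):
        tc.half_system_vector_field(0.0, np.zeros(17), q)


def test_rest_state_is_equilibrium_and_symmetric(params, rest):
    assert np.max(np.abs(tc.network_vector_field(0.0, rest, params))) < 1e-8
    assert np.array_equal(rest, tc.swap_sides(rest))
    # synaptic states are shut at rest
    for side in (0, 17):
        assert np.all(rest[side + 11:side + 17] < 1e-6)
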