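"""Integration-layer tests: determinism, manifold trapping, PIR, SDE."""

import numpy as np
import pytest

import tadcpg as tc
from tadcpg.patterns import detect_spikes
from tadcpg.simulate import (InitiationProtocol, NoiseSpec, PerturbationSpec,
                             StimulusEvent, apply_perturbation, integrate,
                             integrate_on_manifold, integrate_sde)


def test_protocol_breakpoints_and_currents():
    proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=20.0, t1=10.0)
    assert proto.delta == 20.0
    assert set(proto.breakpoints()) == {10.0, 16.0, 30.0, 36.0}
    assert proto.external_currents(12.0).tolist() == [100.0, 0.0, 0.0, 0.0]
    assert proto.external_currents(33.0).tolist() == [0.0, 100.0, 0.0, 0.0]
    assert proto.external_currents(50.0).tolist() == [0.0, 0.0, 0.0, 0.0]


def test_integrate_is_deterministic(params, rest):
    proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=5.0, t1=10.0)
    t1 = integrate(rest, params, proto, t_end=200.0, rtol=1e-8, atol=1e-8)
    t2 = integrate(rest, params, proto, t_end=200.0, rtol=1e-8, atol=1e-8)
    assert np.array_equal(t1.states, t2.states)


def test_rest_is_stable_without_stimulus(params, rest):
    traj = integrate(rest, params, None, t_end=1000.0)
    assert np.max(np.abs(traj.states[-1] - rest)) < 1e-5
    sp = detect_spikes(traj.times, traj.voltage("ldin"))
    assert len(sp.times) == 0


def test_symmetric_initiation_traps_orbit_on_manifold(params, rest):
    """With delta = 0 the left/right traces coincide for the whole run,
    even where the in-phase rhythm is transversally unstable."""
    p = params.with_weights(w_ampa=12.0, w_nmda=10.0, w_inh=55.0)
    proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=0.0, t1=10.0)
    traj = integrate_on_manifold(rest, p, proto, t_end=2000.0)
    assert np.max(np.abs(traj.voltage("ldin") - traj.voltage("rdin"))) == 0.0
    sp = detect_spikes(traj.times, traj.voltage("ldin"))
    assert len(sp.times) > 50          # sustained in-phase rhythm


def test_half_and_full_system_agree_on_manifold(params, rest):
    """Duplicated half-system trajectory matches the full system started
    symmetrically, to integration accuracy, over the first second."""
    p = params.with_weights(w_ampa=10.0, w_nmda=10.0, w_inh=28.0)
    proto = InitiationProtocol.from_delta(A=0.01, d=6.0, delta=0.0, t1=10.0)
    half = integrate_on_manifold(rest, p, proto, t_end=1000.0,
                                 rtol=1e-10, atol=1e-10)
    full = integrate(rest, p, proto, t_end=1000.0, rtol=1e-10, atol=1e-10)
    sp_half = detect_spikes(half.times, half.voltage("ldin")).times
    sp_full = detect_spikes(full.times, full.voltage("ldin")).times
    assert len(sp_half) == len(sp_full)
    # the first-spike latency passes a near-threshold tangency and is
    # ill-conditioned; the cycle structure must agree tightly
    assert abs(sp_half[0] - sp_full[0]) < 0.5
    assert np.max(np.abs(np.diff(sp_half) - np.diff(sp_full))) < 0.02


def test_pir_rebound_spike(params, rest):
    """Release from inhibition against a depolarized background fires a
    rebound spike within ~20 ms (single-neuron protocol)."""
    p = params.with_weights(w_nmda=0.0)
    proto = InitiationProtocol(A=0.0, d=0.0, events=[
        StimulusEvent("ldin", 50.0, 350.0, 0.1),
        StimulusEvent("ldin", 200.0, 60.0, -0.12)])
    traj = integrate(tc.settle_to_rest(p), p, proto, t_end=320.0,
                     rtol=1e-9, atol=1e-9)
    spikes = detect_spikes(traj.times, traj.voltage("ldin")).times
    rebound = spikes[(spikes > 260.0) & (spikes < 280.0)]
    assert len(rebound) == 1
    # and the voltage was genuinely hyperpolarized during the pulse
    i = np.searchsorted(traj.times, 255.0)
    assert traj.voltage("ldin")[i] < -55.0


def test_gating_variables_stay_in_unit_interval(swim60_traj):
    from tadcpg.model import GATING_MASK
    g = swim60_traj.states[:, GATING_MASK]
    assert g.min() > -1e-6 and g.max() < 1 + 1e-6


# ----------------------------------------------------------------------
# stochastic integrator


def test_sde_zero_noise_matches_plain_euler(params, rest):
    proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=0.0, t1=5.0)
    noise = NoiseSpec(phi=0.0, dt=0.01, seed=0)
    traj = integrate_sde(rest, params, proto, noise, t_end=20.0, dt_out=0.1)
    # hand-rolled forward Euler on the same grid
    from tadcpg.model import GATING_MASK
    P = tc.pack_params(params)
    y = rest.copy()
    for k in range(2000):
        dy = tc.network_vector_field(k * 0.01, y, P, stim=proto)
        y = y + dy * 0.01
        y[GATING_MASK] = np.clip(y[GATING_MASK], 0.0, 1.0)
    assert np.max(np.abs(traj.states[-1] - y)) < 1e-6


def test_sde_same_seed_reproducible(params, rest):
    proto = InitiationProtocol.from_delta(A=0.04, d=6.0, delta=0.0, t1=10.0)
    noise = NoiseSpec(phi=0.01, dt=0.01, seed=42)
    t1 = integrate_sde(rest, params, proto, noise, t_end=100.0)
    t2 = integrate_sde(rest, params, proto, noise, t_end=100.0)
    assert np.array_equal(t1.states, t2.states)
    t3 = integrate_sde(rest, params, proto, NoiseSpec(0.01, 0.01, 43),
                       t_end=100.0)
    assert not np.array_equal(t1.states, t3.states)


def test_sde_zero_noise_preserves_symmetry(params, rest):
    p = params.with_weights(w_ampa=10.0, w_nmda=10.0, w_inh=22.2)
    proto = InitiationProtocol.from_delta(A=0.04, d=6.0, delta=0.0, t1=10.0)
    traj = integrate_sde(rest, p, proto, NoiseSpec(phi=0.0, dt=0.01, seed=0),
                         t_end=500.0)
    assert np.max(np.abs(traj.voltage("ldin") - traj.voltage("rdin"))) == 0.0


# ----------------------------------------------------------------------
# perturbation


def test_apply_perturbation_statistics(rest, rng):
    spec = PerturbationSpec(sigma=0.0, seed=1)
    assert np.array_equal(apply_perturbation(rest, spec), rest)
    spec = PerturbationSpec(sigma=1e-3, seed=1)
    y1 = apply_perturbation(rest, spec)
    y2 = apply_perturbation(rest, spec)
    assert np.array_equal(y1, y2)                       # seeded
    assert np.any(y1 != tc.swap_sides(y1))              # symmetry broken
    disp = y1 - rest
    assert np.mean(disp**2) == pytest.approx(1e-6, rel=0.6)
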