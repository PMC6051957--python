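"""Experiment pipelines: grids, bisection, ensembles, symmetry breaking."""

import numpy as np
import pytest

import tadcpg as tc
from tadcpg import experiments as ex
from tadcpg.simulate import InitiationProtocol, NoiseSpec


# ----------------------------------------------------------------------
# specs


def test_grid_spec_validation():
    with pytest.raises(ValueError):
        ex.GridSpec("a", (0, 1), "b", (0, 1), n1=1)
    with pytest.raises(ValueError):
        ex.GridSpec("a", (0, np.inf), "b", (0, 1))
    g = ex.GridSpec("a", (0, 1), "b", (2, 4), n1=3, n2=2)
    assert g.values1().tolist() == [0.0, 0.5, 1.0]
    assert g.values2().tolist() == [2.0, 4.0]


def test_ensemble_seeds_distinct_and_reproducible():
    s1 = ex.EnsembleSpec(n=50, base_seed=9).seeds()
    s2 = ex.EnsembleSpec(n=50, base_seed=9).seeds()
    assert np.array_equal(s1, s2)
    assert len(np.unique(s1)) == 50
    assert np.all(s1 >= 0) and np.all(s1 < 2**31)


def test_boundary_query_validation():
    with pytest.raises(ValueError):
        ex.BoundaryQuery("w_foo", 0, 1, "swim")
    with pytest.raises(ValueError):
        ex.BoundaryQuery("w_inh", 5, 5, "swim")


# ----------------------------------------------------------------------
# bisection machinery


def test_bisect_predicate_toy():
    val = ex.bisect_predicate(lambda x: x > 3.7, 0.0, 10.0, 1e-4)
    assert val == pytest.approx(3.7, abs=1e-3)
    with pytest.raises(ValueError):
        ex.bisect_predicate(lambda x: True, 0.0, 10.0, 1e-4)


def test_criticality_switch_on_synthetic_plane():
    """Hand-built boundary/label structure is recovered exactly."""

    def probe(w_ampa):
        boundary = 20.0 + 2.0 * w_ampa
        return boundary, ("sync2" if w_ampa < 11.05 else "swim")

    res = ex.find_criticality_switch_point(
        tc.default_params(), np.arange(10.0, 12.01, 0.5), probe_fn=probe)
    assert res["found"]
    assert res["w_ampa"] == pytest.approx(11.25)
    assert res["w_inh"] == pytest.approx(20.0 + 2.0 * 11.25, abs=1.0)

    res2 = ex.find_criticality_switch_point(
        tc.default_params(), np.arange(10.0, 11.01, 0.5),
        probe_fn=lambda w: (25.0, "sync2"))
    assert not res2["found"]


# ----------------------------------------------------------------------
# symmetry breaking


def test_symmetry_breaking_zero_sd_is_identity(params):
    q = ex.symmetry_breaking_perturbation(params, sd=0.0, seed=1)
    for nid in ("ldin", "rdin", "lcin", "rcin"):
        assert q.conductances_for(nid) == params.conductances_for(nid)


def test_symmetry_breaking_perturbs_all_conductances(params):
    q = ex.symmetry_breaking_perturbation(params, sd=0.1, seed=2)
    assert not q.symmetric
    for nid in ("ldin", "rdin", "lcin", "rcin"):
        base = params.conductances_for(nid)
        pert = q.conductances_for(nid)
        for g in base:
            assert pert[g] != base[g]
            assert pert[g] >= 0.0
    # deterministic given the seed
    q2 = ex.symmetry_breaking_perturbation(params, sd=0.1, seed=2)
    assert q2.conductance_overrides == q.conductance_overrides


def test_symmetry_breaking_redraws_negative(params):
    with pytest.warns(UserWarning):
        q = ex.symmetry_breaking_perturbation(params, sd=50.0, seed=3)
    for nid in ("ldin", "rdin", "lcin", "rcin"):
        assert all(v >= 0 for v in q.conductances_for(nid).values())


# ----------------------------------------------------------------------
# physiological ranges


@pytest.mark.parametrize("n_min,n_max,unitary,expected", [
    (15, 17, 0.6, (9.0, 10.2)),
    (13, 21, 0.75, (9.75, 15.75)),
    (5, 5, 0.3, (1.5, 1.5)),
])
def test_physiological_range(n_min, n_max, unitary, expected):
    lo, hi = ex.physiological_range(n_min, n_max, unitary)
    assert lo == pytest.approx(expected[0])
    assert hi == pytest.approx(expected[1])


def test_physiological_range_rejects_bad_input():
    with pytest.raises(ValueError):
        ex.physiological_range(10, 5, 0.6)
    with pytest.raises(ValueError):
        ex.physiological_range(1, 2, -0.1)


# ----------------------------------------------------------------------
# pipelines (small, fast instances)


def test_noise_ensemble_zero_phi_never_transitions(fig8_weights, rest):
    p = fig8_weights.with_weights(w_inh=22.2)
    proto = InitiationProtocol.from_delta(A=0.04, d=6.0, delta=0.0, t1=10.0)
    spec = ex.EnsembleSpec(n=2, base_seed=5, noise=NoiseSpec(phi=0.0, dt=0.01),
                           duration=800.0)
    frame = ex.noise_transition_ensemble(p, spec, proto, rest=rest)
    assert (frame["outcome"] == "no-transition").all()


def test_initiation_map_tiny_grid(fig8_weights, rest):
    p = fig8_weights.with_weights(w_inh=28.0)
    grid = ex.GridSpec("delta", (0.0, 2.0), "d", (1.0, 6.0), n1=2, n2=2,
                       duration=900.0)
    frame = ex.initiation_space_map(p, grid, A=0.01, rest=rest, rtol=1e-8)
    assert len(frame) == 4
    assert set(frame.columns) >= {"delta", "d", "category", "period"}
    assert frame["category"].isin(
        ["rest", "swim", "sync", "sync2", "other", "error"]).all()
    # the 1-ms column cannot charge the membrane to threshold
    short = frame[frame["d"] == 1.0]
    assert (short["category"] == "rest").all()


def test_bistability_at_fig3_parameters(params, rest):
    """Same weights, different initiation: anti-phase vs in-phase rhythm."""
    p = params.with_weights(w_ampa=12.0, w_nmda=10.0, w_inh=23.0)
    swim = ex.simulate_episode(
        p, InitiationProtocol.from_delta(A=0.1, d=6.0, delta=140.0, t1=10.0),
        t_end=3000.0, y0=rest)
    sync = ex.simulate_episode(
        p, InitiationProtocol.from_delta(A=0.1, d=6.0, delta=0.0, t1=10.0),
        t_end=3000.0, y0=rest)
    assert ex.classify_episode(swim).category == "swim"
    lab = ex.classify_episode(sync)
    assert lab.category == "sync" and lab.period > 0
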