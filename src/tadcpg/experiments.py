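"""The numerical experiments: initiation-space and parameter-plane maps,
stability-boundary bisection, stochastic transition ensembles, perturb-and-
release and mid-cycle switching protocols, and symmetry breaking.

Every randomized operation takes an explicit integer seed; grid and
ensemble results are returned as tidy pandas DataFrames ready for CSV
export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import NetworkParams
from .patterns import (AttractorLabel, ClassificationConfig, classify_attractor,
                       detect_transition_time, spike_trains)
from .simulate import (InitiationProtocol, NoiseSpec, PerturbationSpec,
                       StimulusEvent, Trajectory, apply_perturbation, integrate,
                       integrate_on_manifold, integrate_sde, settle_to_rest)

__all__ = [
    "GridSpec", "BoundaryQuery", "EnsembleSpec", "simulate_episode",
    "classify_episode", "initiation_space_map", "parameter_plane_map",
    "bisect_predicate", "bisect_stability_boundary",
    "find_criticality_switch_point",
    "noise_transition_ensemble", "perturb_and_release", "midcycle_switch",
    "symmetry_breaking_perturbation", "physiological_range",
]


# ----------------------------------------------------------------------
# specs


@dataclass
class GridSpec:
    """Uniform 2-D grid of experiment conditions."""

    axis1: str
    range1: tuple[float, float]
    axis2: str
    range2: tuple[float, float]
    n1: int = 32
    n2: int = 32
    duration: float = 3000.0

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("grid needs at least 2 points per axis")
        for r in (self.range1, self.range2):
            if not all(np.isfinite(r)):
                raise ValueError("grid ranges must be finite")

    def values1(self) -> np.ndarray:
        return np.linspace(*self.range1, self.n1)

    def values2(self) -> np.ndarray:
        return np.linspace(*self.range2, self.n2)


@dataclass
class BoundaryQuery:
    """Bisection query for a stability boundary along one synaptic weight."""

    param: str                       # 'w_inh' | 'w_ampa' | 'w_nmda'
    lo: float
    hi: float
    category: str                    # attractor category that defines the predicate
    tolerance: float = 0.02          # nS

    def __post_init__(self):
        if self.param not in ("w_inh", "w_ampa", "w_nmda"):
            raise ValueError(f"unknown scan parameter {self.param!r}")
        if self.lo >= self.hi:
            raise ValueError("bracket must satisfy lo < hi")


@dataclass
class EnsembleSpec:
    """Seeded ensemble of stochastic simulations."""

    n: int = 100
    base_seed: int = 0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    duration: float = 2000.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one replicate")

    def seeds(self) -> np.ndarray:
        # distinct per-replicate seeds derived from the base seed
        ss = np.random.SeedSequence(self.base_seed)
        return np.array([int(s) % (2**31 - 1)
                         for s in ss.generate_state(self.n)], dtype=np.int64)


# ----------------------------------------------------------------------
# shared episode runner


def simulate_episode(p: NetworkParams, protocol: InitiationProtocol,
                     t_end: float = 3000.0, y0=None,
                     rtol: float = 1e-10, atol: float = 1e-10) -> Trajectory:
    """Run one deterministic episode from rest (or ``y0``).

    Exactly symmetric episodes are integrated on the in-phase manifold,
    which the symmetry makes invariant; asymmetric ones use the full
    34-dimensional system.
    """
    if y0 is None:
        y0 = settle_to_rest(p)
    if protocol.symmetric and p.symmetric:
        return integrate_on_manifold(y0, p, protocol, t_end=t_end,
                                     rtol=rtol, atol=atol)
    return integrate(y0, p, protocol, t_end=t_end, rtol=rtol, atol=atol)


def classify_episode(traj: Trajectory,
                     config: ClassificationConfig | None = None) -> AttractorLabel:
    config = config or ClassificationConfig()
    trains = spike_trains(traj, config)
    t_end = traj.times[-1]
    return classify_attractor(trains["ldin"], trains["rdin"], config,
                              window=(max(0.0, t_end - config.window), t_end))


# ----------------------------------------------------------------------
# maps


def initiation_space_map(p: NetworkParams, grid: GridSpec | None = None,
                         A: float = 0.01, t1: float = 10.0,
                         config: ClassificationConfig | None = None,
                         rtol: float = 1e-8, rest=None,
                         progress: bool = False) -> pd.DataFrame:
    """Attractor label and period over the (delta, d) initiation plane.

    Each pixel initiates the network from rest with the paired-step
    protocol and classifies the trajectory tail after ``grid.duration``.
    """
    grid = grid or GridSpec("delta", (0.0, 30.0), "d", (0.0, 20.0),
                            duration=3000.0)
    if rest is None:
        rest = settle_to_rest(p)
    rows = []
    it = 0
    for delta in grid.values1():
        for d in grid.values2():
            it += 1
            proto = InitiationProtocol.from_delta(A=A, d=d, delta=delta, t1=t1)
            try:
                traj = simulate_episode(p, proto, t_end=grid.duration, y0=rest,
                                        rtol=rtol, atol=rtol)
                lab = classify_episode(traj, config)
                rows.append((delta, d, lab.category, lab.period, ""))
            except RuntimeError as err:       # solver failure is per-pixel data
                rows.append((delta, d, "error", np.nan, str(err)))
            if progress and it % 50 == 0:
                print(f"  initiation map: {it} pixels done")
    return pd.DataFrame(rows, columns=["delta", "d", "category", "period",
                                       "note"])


def parameter_plane_map(p: NetworkParams, grid: GridSpec,
                        protocol: InitiationProtocol,
                        config: ClassificationConfig | None = None,
                        rtol: float = 1e-8, rest=None,
                        progress: bool = False) -> pd.DataFrame:
    """Attractor label/period over a plane of two synaptic strengths.

    ``grid.axis1``/``axis2`` name two of w_inh, w_ampa, w_nmda; the same
    initiation protocol is applied at every pixel.
    """
    rows = []
    it = 0
    for v1 in grid.values1():
        for v2 in grid.values2():
            it += 1
            pp = p.with_weights(**{grid.axis1: v1, grid.axis2: v2})
            try:
                r0 = rest if rest is not None else None
                traj = simulate_episode(pp, protocol, t_end=grid.duration,
                                        y0=r0, rtol=rtol, atol=rtol)
                lab = classify_episode(traj, config)
                rows.append((v1, v2, lab.category, lab.period, ""))
            except RuntimeError as err:
                rows.append((v1, v2, "error", np.nan, str(err)))
            if progress and it % 20 == 0:
                print(f"  parameter map: {it} pixels done")
    return pd.DataFrame(rows, columns=[grid.axis1, grid.axis2, "category",
                                       "period", "note"])


# ----------------------------------------------------------------------
# boundary location


def bisect_predicate(pred, lo: float, hi: float, tol: float) -> float:
    """Generic bisection of a boolean predicate that differs at lo and hi."""
    p_lo, p_hi = pred(lo), pred(hi)
    if p_lo == p_hi:
        raise ValueError("predicate identical at both bracket ends")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pred(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bisect_stability_boundary(p: NetworkParams, query: BoundaryQuery,
                              protocol: InitiationProtocol,
                              t_end: float = 3000.0,
                              t_end_near: float = 8000.0,
                              config: ClassificationConfig | None = None,
                              rtol: float = 1e-10, rest=None,
                              verbose: bool = False):
    """Bisect one synaptic weight to a stability boundary.

    The predicate is "the episode's tail classifies as ``query.category``".
    Runs are lengthened to ``t_end_near`` once the bracket narrows below
    ten tolerances, because transients diverge near subcritical
    bifurcations.  Returns (boundary, label_lo, label_hi).

    Raises ValueError when the predicate does not differ at the bracket
    ends (no boundary of this type inside the bracket).
    """
    if rest is None:
        rest = settle_to_rest(p)

    labels: dict[float, AttractorLabel] = {}

    def run(value: float, horizon: float) -> AttractorLabel:
        pp = p.with_weights(**{query.param: value})
        traj = simulate_episode(pp, protocol, t_end=horizon, y0=rest,
                                rtol=rtol, atol=rtol)
        lab = classify_episode(traj, config)
        labels[value] = lab
        if verbose:
            print(f"    {query.param}={value:.4f}: {lab.category} "
                  f"T={lab.period:.1f}")
        return lab

    pred_lo = run(query.lo, t_end).category == query.category
    pred_hi = run(query.hi, t_end).category == query.category
    if pred_lo == pred_hi:
        raise ValueError(
            f"predicate '{query.category}' identical at both bracket ends "
            f"({query.param}={query.lo}: {labels[query.lo].category}, "
            f"{query.param}={query.hi}: {labels[query.hi].category}); "
            "no boundary in bracket")
    lo, hi = query.lo, query.hi
    while hi - lo > query.tolerance:
        mid = 0.5 * (lo + hi)
        horizon = t_end_near if (hi - lo) < 10 * query.tolerance else t_end
        pred_mid = run(mid, horizon).category == query.category
        if pred_mid == pred_lo:
            lo = mid
        else:
            hi = mid
    boundary = 0.5 * (lo + hi)
    return boundary, labels[query.lo], labels[query.hi]


def find_criticality_switch_point(p: NetworkParams,
                                  scan_values: np.ndarray,
                                  scan_param: str = "w_ampa",
                                  bracket: tuple[float, float] = (22.0, 35.0),
                                  beyond: float = 1.0,
                                  protocol: InitiationProtocol | None = None,
                                  tolerance: float = 0.05,
                                  t_end: float = 5000.0,
                                  verbose: bool = False,
                                  probe_fn=None):
    """Locate the criticality switch on the upper synchrony boundary.

    For each value of ``scan_param``, the upper in-phase stability
    boundary in w_inh is located by bisection (near-symmetric initiation)
    and the attractor just beyond it is classified.  Returns a dict with
    the switch coordinates (boundary w_inh at the scan value where the
    just-beyond attractor changes between 'swim' and 'sync2'), or
    ``{"found": False, ...}`` with the per-scan records when no switch
    (or no boundary) exists in range.

    ``probe_fn(scan_value) -> (boundary_w_inh, beyond_category)`` may
    replace the simulation probe (raising ValueError for no boundary).
    """
    protocol = protocol or InitiationProtocol.from_delta(A=0.1, d=6.0,
                                                         delta=1e-4, t1=10.0)
    records = []
    rest_cache = None if probe_fn else settle_to_rest(p)

    def default_probe(v: float):
        pp = p.with_weights(**{scan_param: float(v)})
        query = BoundaryQuery("w_inh", bracket[0], bracket[1], "sync",
                              tolerance=tolerance)
        boundary, _, _ = bisect_stability_boundary(
            pp, query, protocol, t_end=t_end, t_end_near=t_end,
            rest=rest_cache, verbose=verbose)
        pb = pp.with_weights(w_inh=boundary + beyond)
        traj = simulate_episode(pb, protocol, t_end=t_end, y0=rest_cache)
        return boundary, classify_episode(traj).category

    probe = probe_fn or default_probe
    for v in scan_values:
        try:
            boundary, beyond_cat = probe(float(v))
        except ValueError as err:
            records.append({"scan": float(v), "boundary": np.nan,
                            "beyond": "no-boundary", "note": str(err)})
            continue
        records.append({"scan": float(v), "boundary": boundary,
                        "beyond": beyond_cat, "note": ""})
        if verbose:
            print(f"  {scan_param}={v}: boundary={boundary:.2f} "
                  f"beyond={beyond_cat}")
    cats = [r["beyond"] for r in records]
    for a, b in zip(records[:-1], records[1:]):
        pair = {a["beyond"], b["beyond"]}
        if pair == {"swim", "sync2"}:
            return {"found": True,
                    "w_inh": 0.5 * (a["boundary"] + b["boundary"]),
                    scan_param: 0.5 * (a["scan"] + b["scan"]),
                    "records": records}
    return {"found": False, "records": records, "categories": cats}


# ----------------------------------------------------------------------
# stochastic ensembles and perturbation protocols


def noise_transition_ensemble(p: NetworkParams, spec: EnsembleSpec,
                              protocol: InitiationProtocol | None = None,
                              config: ClassificationConfig | None = None,
                              rest=None, progress: bool = False) -> pd.DataFrame:
    """Distribution of synchrony-to-swimming transition times under noise.

    Each replicate integrates the stochastic model (Euler-Maruyama) from
    rest with an in-phase initiation, classifies the endpoint (swim /
    rest / still synchronous) and records the transition time.
    """
    protocol = protocol or InitiationProtocol.from_delta(A=0.04, d=6.0,
                                                         delta=0.0, t1=10.0)
    config = config or ClassificationConfig()
    if rest is None:
        rest = settle_to_rest(p)
    rows = []
    for i, seed in enumerate(spec.seeds()):
        noise = NoiseSpec(phi=spec.noise.phi, dt=spec.noise.dt, seed=int(seed))
        traj = integrate_sde(rest, p, protocol, noise, t_end=spec.duration)
        trains = spike_trains(traj, config)
        t_end = traj.times[-1]
        tail = classify_attractor(trains["ldin"], trains["rdin"], config,
                                  window=(t_end - 300.0, t_end))
        if tail.category == "swim":
            outcome = "to-swim"
            t_switch = detect_transition_time(trains["ldin"], trains["rdin"],
                                              t_end, config=config)
        elif tail.category == "rest":
            outcome = "to-rest"
            t_switch = math.inf
        else:
            outcome = "no-transition"
            t_switch = math.inf
        rows.append((int(seed), outcome, t_switch, tail.category, tail.period))
        if progress and (i + 1) % 20 == 0:
            print(f"  ensemble: {i + 1}/{spec.n} replicates")
    return pd.DataFrame(rows, columns=["seed", "outcome", "transition_time",
                                       "tail_category", "tail_period"])


def perturb_and_release(p: NetworkParams, spec: PerturbationSpec,
                        protocol: InitiationProtocol | None = None,
                        t_end: float = 3000.0,
                        config: ClassificationConfig | None = None):
    """In-phase episode, instantaneous Gaussian kick at t*, then release.

    The pre-kick orbit lies in the in-phase manifold (delta = 0); the
    kick moves it off the manifold, after which the full system decides
    where the trajectory goes.  Returns (trajectory, transition_time).
    """
    protocol = protocol or InitiationProtocol.from_delta(A=0.04, d=6.0,
                                                         delta=0.0, t1=10.0)
    if not protocol.symmetric:
        raise ValueError("perturb-and-release requires a symmetric protocol")
    rest = settle_to_rest(p)
    pre = integrate_on_manifold(rest, p, protocol, t_end=spec.t_star)
    y_star = apply_perturbation(pre.states[-1], spec)
    post = integrate(y_star, p, None, t_end=t_end - spec.t_star)
    times = np.concatenate([pre.times, post.times[1:] + spec.t_star])
    states = np.vstack([pre.states, post.states[1:]])
    traj = Trajectory(times=times, states=states, protocol=protocol,
                      meta={"t_star": spec.t_star, "sigma": spec.sigma,
                            "seed": spec.seed})
    config = config or ClassificationConfig()
    trains = spike_trains(traj, config)
    t_switch = detect_transition_time(trains["ldin"], trains["rdin"],
                                      times[-1], config=config)
    return traj, t_switch


def midcycle_switch(p: NetworkParams,
                    protocol: InitiationProtocol | None = None,
                    pulse_amplitude: float = 0.45, pulse_duration: float = 5.0,
                    t_pulse_near: float = 500.0, t_end: float = 2000.0,
                    config: ClassificationConfig | None = None):
    """Inject a brief pulse into the left dIN at a right-dIN firing time.

    Mimics the experimental induction of (double-)synchrony from
    swimming: the pulse evokes an extra left spike nearly synchronous
    with the right side.  Returns (trajectory, pulse_onset,
    window_labels DataFrame).
    """
    protocol = protocol or InitiationProtocol.from_delta(A=0.04, d=6.0,
                                                         delta=50.0, t1=10.0)
    config = config or ClassificationConfig()
    rest = settle_to_rest(p)
    probe = integrate(rest, p, protocol, t_end=t_pulse_near + 200.0)
    trains = spike_trains(probe, config)
    r_spikes = trains["rdin"].times
    if len(r_spikes) == 0:
        raise RuntimeError("no right-dIN spikes; swimming was not established")
    t_pulse = float(r_spikes[np.argmin(np.abs(r_spikes - t_pulse_near))])
    proto2 = InitiationProtocol(
        A=protocol.A, d=protocol.d, t1=protocol.t1, t2=protocol.t2,
        events=list(protocol.events) + [
            StimulusEvent("ldin", t_pulse, pulse_duration, pulse_amplitude)])
    traj = integrate(rest, p, proto2, t_end=t_end)
    trains2 = spike_trains(traj, config)
    from .patterns import window_labels as _wl
    centers, labels = _wl(trains2["ldin"], trains2["rdin"], t_end,
                          config=config)
    frame = pd.DataFrame({"t_center": centers, "category": labels})
    return traj, t_pulse, frame


# ----------------------------------------------------------------------
# symmetry breaking and physiology


def symmetry_breaking_perturbation(p: NetworkParams, sd: float = 0.1,
                                   seed: int = 0,
                                   relative: bool = False) -> NetworkParams:
    """Perturb every maximal conductance independently (Gaussian, sd nS).

    Each of the 16 conductances (g_lk, g_Na, g_Kf, g_Ks of the four
    neurons) receives an independent draw; negative results are redrawn.
    ``relative=True`` scales the sd by each conductance instead.
    Synaptic and kinetic parameters are untouched.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    q = p.copy()
    overrides: dict[str, dict[str, float]] = {}
    n_redraw = 0
    from .params import NEURON_IDS
    for nid in NEURON_IDS:
        base = q.conductances_for(nid)
        pert = {}
        for gname, gval in base.items():
            scale = sd * gval if relative else sd
            new = gval + scale * rng.standard_normal()
            while new < 0:
                n_redraw += 1
                new = gval + scale * rng.standard_normal()
            pert[gname] = float(new)
        overrides[nid] = pert
    q.conductance_overrides = overrides
    q.validate()
    if n_redraw:
        import warnings
        warnings.warn(f"redrew {n_redraw} negative conductance perturbations")
    return q


def physiological_range(n_min: int, n_max: int, unitary: float) -> tuple[float, float]:
    """Range of a pooled synaptic strength from convergence counts.

    The pooled strength of one modelled synapse stands in for n
    convergent unitary synapses of maximal strength ``unitary`` (nS);
    the plausible range is simply (n_min*unitary, n_max*unitary).
    """
    if n_min > n_max:
        raise ValueError("n_min must not exceed n_max")
    if unitary < 0:
        raise ValueError("unitary strength must be >= 0")
    return (n_min * unitary, n_max * unitary)
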