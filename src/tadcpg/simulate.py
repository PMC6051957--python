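"""Deterministic and stochastic integration of the reduced CPG.

Deterministic runs use a stiff-capable adaptive solver (LSODA) with the
integration restarted at every stimulus edge so the solver never steps
across a discontinuity.  Stochastic runs use fixed-step Euler-Maruyama
with additive noise of equal amplitude on all 34 components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import model
from .model import GATING_MASK, N_HALF, N_STATE, _rhs, _rhs_half, pack_params
from .params import NEURON_IDS, NetworkParams

NA_TO_PA = 1000.0


@dataclass
class StimulusEvent:
    """A step current injected into one neuron (amplitude in nA)."""

    target: str              # one of 'ldin', 'rdin', 'lcin', 'rcin'
    onset: float             # ms
    duration: float          # ms
    amplitude: float         # nA (negative = hyperpolarizing)

    def __post_init__(self):
        if self.target not in NEURON_IDS:
            raise ValueError(f"unknown target neuron {self.target!r}")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass
class InitiationProtocol:
    """Paired step currents to the two dINs that start an episode.

    Both steps share amplitude ``A`` (nA) and duration ``d`` (ms); the
    left one starts at ``t1`` and the right one at ``t2 = t1 + delta``.
    """

    A: float = 0.1           # nA
    d: float = 6.0           # ms
    t1: float = 0.0          # ms
    t2: float | None = None  # ms; defaults to t1 (delta = 0)
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.t2 is None:
            self.t2 = self.t1
        if self.d < 0 or self.A < 0:
            raise ValueError("A and d must be >= 0")

    @property
    def delta(self) -> float:
        return self.t2 - self.t1

    @classmethod
    def from_delta(cls, A: float, d: float, delta: float, t1: float = 10.0,
                   events=()) -> "InitiationProtocol":
        return cls(A=A, d=d, t1=t1, t2=t1 + delta, events=list(events))

    # ------------------------------------------------------------------
    def breakpoints(self) -> np.ndarray:
        """Times at which the external current is discontinuous."""
        pts = [self.t1, self.t1 + self.d, self.t2, self.t2 + self.d]
        for ev in self.events:
            pts += [ev.onset, ev.onset + ev.duration]
        return np.unique(np.asarray(pts, dtype=float))

    def external_currents(self, t: float) -> np.ndarray:
        """pA injected into (ldin, rdin, lcin, rcin) at time t."""
        i = np.zeros(4)
        if self.t1 <= t < self.t1 + self.d:
            i[0] += self.A * NA_TO_PA
        if self.t2 <= t < self.t2 + self.d:
            i[1] += self.A * NA_TO_PA
        for ev in self.events:
            if ev.onset <= t < ev.onset + ev.duration:
                i[NEURON_IDS.index(ev.target)] += ev.amplitude * NA_TO_PA
        return i

    @property
    def symmetric(self) -> bool:
        return self.delta == 0.0 and not self.events


ZERO_PROTOCOL = InitiationProtocol(A=0.0, d=0.0, t1=0.0)


@dataclass
class NoiseSpec:
    """Additive white-noise amplitude and Euler-Maruyama step."""

    phi: float = 0.01
    dt: float = 0.01         # ms
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


@dataclass
class PerturbationSpec:
    """Instantaneous Gaussian kick applied to every state component."""

    t_star: float = 300.0    # ms
    sigma: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class Trajectory:
    """Time-stamped solution of the 34-dimensional system."""

    times: np.ndarray        # (n,) ms
    states: np.ndarray       # (n, 34)
    protocol: InitiationProtocol | None = None
    meta: dict = field(default_factory=dict)

    def voltage(self, neuron: str) -> np.ndarray:
        return self.states[:, model.V_INDEX[neuron]]

    def window(self, t_from: float, t_to: float | None = None) -> "Trajectory":
        t_to = self.times[-1] if t_to is None else t_to
        sel = (self.times >= t_from) & (self.times <= t_to)
        return Trajectory(self.times[sel], self.states[sel], self.protocol, self.meta)

    # ------------------------------------------------------------------
    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("states", data=self.states)
            for k, v in self.meta.items():
                if isinstance(v, (int, float, str)):
                    fh.attrs[k] = v
            if self.protocol is not None:
                fh.attrs["protocol_A_nA"] = self.protocol.A
                fh.attrs["protocol_d_ms"] = self.protocol.d
                fh.attrs["protocol_t1_ms"] = self.protocol.t1
                fh.attrs["protocol_t2_ms"] = self.protocol.t2

    @classmethod
    def load_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(times=fh["times"][:], states=fh["states"][:],
                       meta=dict(fh.attrs))

    def voltages_frame(self):
        """Tidy voltage table (time plus one column per neuron)."""
        import pandas as pd

        data = {"time_ms": self.times}
        for nid in NEURON_IDS:
            data[f"v_{nid}"] = self.voltage(nid)
        return pd.DataFrame(data)


# ----------------------------------------------------------------------
# resting state


def resting_guess(p: NetworkParams) -> np.ndarray:
    """Initial guess: leak reversal, gating at steady state, synapses off."""
    y = np.zeros(N_STATE)
    for side in (0, model.N_HALF):
        v_d, v_c = p.dIN.e_lk, p.cIN.e_lk
        y[side + model.DIN_V] = v_d
        for g, gate in enumerate(("m", "h", "f", "l", "r")):
            r = p.dIN.rates[gate]
            a = model.rate_fn(v_d, r.alpha)
            b = model.rate_fn(v_d, r.beta)
            y[side + model.DIN_M + g] = a / (a + b) if a + b > 0 else 0.0
        y[side + model.CIN_V] = v_c
        for g, gate in enumerate(("m", "h", "f", "l")):
            r = p.cIN.rates[gate]
            a = model.rate_fn(v_c, r.alpha)
            b = model.rate_fn(v_c, r.beta)
            y[side + model.CIN_M + g] = a / (a + b) if a + b > 0 else 0.0
    return y


def settle_to_rest(p: NetworkParams, t_settle: float = 500.0,
                   t_max: float = 2000.0, tol: float = 1e-8) -> np.ndarray:
    """Locate the stable resting equilibrium with zero stimulus.

    Integrates from a leak-reversal guess, then Newton-polishes; raises
    if the field norm has not dropped below ``tol`` per component within
    ``t_max`` ms of settling.
    """
    P = pack_params(p)
    zero4 = np.zeros(4)
    dy = np.empty(N_STATE)

    def f(y):
        _rhs(y, dy, P, zero4)
        return dy.copy()

    y = resting_guess(p)
    t = 0.0
    while t < t_max:
        sol = solve_ivp(lambda tt, yy: f(yy), (0.0, t_settle), y,
                        method="LSODA", rtol=1e-10, atol=1e-12)
        y = sol.y[:, -1]
        t += t_settle
        polished = root(f, y, method="hybr", tol=1e-13)
        if polished.success and np.max(np.abs(f(polished.x))) < tol:
            y_rest = polished.x
            if p.symmetric:
                # make the equilibrium exactly swap-symmetric
                y_rest = 0.5 * (y_rest + model.swap_sides(y_rest))
                if np.max(np.abs(f(y_rest))) >= tol:
                    continue
            return y_rest
    raise RuntimeError(
        f"no resting equilibrium found within {t_max} ms "
        f"(residual {np.max(np.abs(f(y))):.3g})")


# ----------------------------------------------------------------------
# deterministic integration


def integrate(y0: np.ndarray, p: NetworkParams | np.ndarray,
              protocol: InitiationProtocol | None = None,
              t_end: float = 3000.0, dt_out: float = 0.1,
              rtol: float = 1e-10, atol: float = 1e-10,
              method: str = "LSODA") -> Trajectory:
    """Integrate the deterministic model under a stimulation protocol.

    Output is sampled on the uniform grid k*dt_out; the solve is split
    at every stimulus edge.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    protocol = protocol or ZERO_PROTOCOL
    P = p if isinstance(p, np.ndarray) else pack_params(p)

    edges = protocol.breakpoints()
    edges = edges[(edges > 0) & (edges < t_end)]
    seg_bounds = np.concatenate([[0.0], edges, [t_end]])

    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    times_out = [np.array([0.0])]
    states_out = [np.asarray(y0, dtype=float)[None, :]]

    dy = np.empty(N_STATE)

    y = np.asarray(y0, dtype=float)
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if b - a <= 0:
            continue
        iext = protocol.external_currents(0.5 * (a + b))

        def rhs(t, yy, iext=iext):
            _rhs(yy, dy, P, iext)
            return dy

        t_eval = t_grid[(t_grid > a + 1e-12) & (t_grid <= b + 1e-12)]
        # always evaluate the exact segment end so the next segment
        # continues from b even when b is off the output grid
        n_keep = len(t_eval)
        if n_keep == 0 or t_eval[-1] < b - 1e-9:
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"solver failed at t = {sol.t[-1]:.3f} ms: "
                               f"{sol.message}")
        y = sol.y[:, -1].copy()
        if n_keep:
            times_out.append(sol.t[:n_keep])
            states_out.append(sol.y[:, :n_keep].T)

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    return Trajectory(times=times, states=states, protocol=protocol,
                      meta={"method": method, "rtol": rtol, "atol": atol})


def integrate_on_manifold(y0: np.ndarray, p: NetworkParams,
                          protocol: InitiationProtocol | None = None,
                          t_end: float = 3000.0, dt_out: float = 0.1,
                          rtol: float = 1e-10, atol: float = 1e-10,
                          method: str = "LSODA") -> Trajectory:
    """Integrate an exactly symmetric episode on the in-phase manifold.

    A symmetric protocol (delta = 0, no events) with symmetric parameters
    keeps the orbit in Y+ = {y_L = y_R}; integrating the 17-dimensional
    half system and embedding the result realizes this invariance exactly
    instead of relying on the full solver preserving symmetry to round-off.
    Returns a Trajectory in the full 34-dimensional layout.
    """
    protocol = protocol or ZERO_PROTOCOL
    if not protocol.symmetric:
        raise ValueError("manifold integration requires a symmetric protocol")
    if not p.symmetric:
        raise ValueError("manifold integration requires symmetric parameters")
    P = pack_params(p)
    y0 = np.asarray(y0, dtype=float)
    if y0.shape == (N_STATE,):
        if np.max(np.abs(y0 - model.swap_sides(y0))) > 1e-9:
            raise ValueError("initial state is not swap-symmetric")
        y_half = 0.5 * (y0[:N_HALF] + y0[N_HALF:])
    elif y0.shape == (N_HALF,):
        y_half = y0.copy()
    else:
        raise ValueError("state must have 34 (symmetric) or 17 components")

    edges = protocol.breakpoints()
    edges = edges[(edges > 0) & (edges < t_end)]
    seg_bounds = np.concatenate([[0.0], edges, [t_end]])
    t_grid = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    times_out = [np.array([0.0])]
    states_out = [y_half[None, :]]
    dy = np.empty(N_HALF)
    y = y_half
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if b - a <= 0:
            continue
        iext2 = protocol.external_currents(0.5 * (a + b))[[0, 2]]

        def rhs(t, yy, iext2=iext2):
            _rhs_half(yy, dy, P, iext2)
            return dy

        t_eval = t_grid[(t_grid > a + 1e-12) & (t_grid < b - 1e-12)]
        n_keep = len(t_eval)
        t_eval = np.append(t_eval, b)    # land exactly on the segment end
        sol = solve_ivp(rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"solver failed at t = {sol.t[-1]:.3f} ms")
        y = sol.y[:, -1].copy()
        if n_keep:
            times_out.append(sol.t[:n_keep])
            states_out.append(sol.y[:, :n_keep].T)
    times_out.append(np.array([t_end]))
    states_out.append(y[None, :])
    times = np.concatenate(times_out)
    half_states = np.vstack(states_out)
    states = np.hstack([half_states, half_states])
    return Trajectory(times=times, states=states, protocol=protocol,
                      meta={"method": method, "rtol": rtol, "atol": atol,
                            "manifold": True})


# ----------------------------------------------------------------------
# stochastic integration (Euler-Maruyama)


@njit(cache=True)
def _em_loop(y, P, dt, n_steps, rec_stride, phi, seed,
             seg_end_step, seg_iext, out_states, clip_mask):
    np.random.seed(seed)
    sqdt = math.sqrt(dt)
    dy = np.empty(y.shape[0])
    iext = np.empty(4)
    seg = 0
    n_clip = 0
    k_out = 0
    for step in range(n_steps):
        while step >= seg_end_step[seg]:
            seg += 1
        for j in range(4):
            iext[j] = seg_iext[seg, j]
        _rhs(y, dy, P, iext)
        if phi > 0.0:
            for j in range(y.shape[0]):
                y[j] += dy[j] * dt + phi * sqdt * np.random.normal()
        else:
            for j in range(y.shape[0]):
                y[j] += dy[j] * dt
        for j in range(y.shape[0]):
            if clip_mask[j]:
                if y[j] < 0.0:
                    y[j] = 0.0
                    n_clip += 1
                elif y[j] > 1.0:
                    y[j] = 1.0
                    n_clip += 1
            elif abs(y[j]) > 500.0:
                return -(step + 1), n_clip, k_out
        if (step + 1) % rec_stride == 0:
            for j in range(y.shape[0]):
                out_states[k_out, j] = y[j]
            k_out += 1
    return 0, n_clip, k_out


def integrate_sde(y0: np.ndarray, p: NetworkParams | np.ndarray,
                  protocol: InitiationProtocol | None = None,
                  noise: NoiseSpec | None = None,
                  t_end: float = 2000.0, dt_out: float = 0.1) -> Trajectory:
    """Euler-Maruyama integration du = f(u) dt + phi dW on all 34 states.

    Gating and synaptic variables are clipped to [0, 1] after each step
    (clip count reported in ``meta['n_clipped']``).  phi = 0 reduces to
    fixed-step deterministic Euler.
    """
    noise = noise or NoiseSpec()
    protocol = protocol or ZERO_PROTOCOL
    P = p if isinstance(p, np.ndarray) else pack_params(p)
    dt = noise.dt
    rec_stride = int(round(dt_out / dt))
    if abs(rec_stride * dt - dt_out) > 1e-9:
        raise ValueError("noise.dt must divide dt_out")
    n_steps = int(round(t_end / dt))

    edges = protocol.breakpoints()
    edges = edges[(edges > 0) & (edges < t_end)]
    seg_bounds = np.concatenate([[0.0], edges, [t_end]])
    seg_end_step = np.array(
        [int(round(b / dt)) for b in seg_bounds[1:]], dtype=np.int64)
    seg_end_step[-1] = n_steps + 1
    seg_iext = np.vstack([protocol.external_currents(0.5 * (a + b))
                          for a, b in zip(seg_bounds[:-1], seg_bounds[1:])])

    n_out = n_steps // rec_stride
    out_states = np.empty((n_out, N_STATE))
    y = np.array(y0, dtype=float)
    status, n_clip, k_out = _em_loop(
        y, P, dt, n_steps, rec_stride, noise.phi, noise.seed,
        seg_end_step, seg_iext, out_states, GATING_MASK)
    if status < 0:
        t_fail = -status * dt
        raise RuntimeError(f"stochastic trajectory diverged at t = {t_fail:.2f} ms")

    times = dt_out * np.arange(1, k_out + 1)
    times = np.concatenate([[0.0], times])
    states = np.vstack([np.asarray(y0, dtype=float)[None, :], out_states[:k_out]])
    return Trajectory(times=times, states=states, protocol=protocol,
                      meta={"method": "euler-maruyama", "phi": noise.phi,
                            "dt": dt, "seed": noise.seed, "n_clipped": n_clip})


def apply_perturbation(y: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Add an independent Gaussian offset (sd = sigma) to every component."""
    rng = np.random.default_rng(spec.seed)
    return np.asarray(y, dtype=float) + spec.sigma * rng.standard_normal(len(y))
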