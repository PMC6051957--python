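"""Spike detection and attractor classification.

Voltage trajectories are reduced to spike trains (interpolated upward
threshold crossings) and the left/right dIN trains are classified into
the rhythm categories of the reduced CPG:

``rest``   no sustained firing (period 0);
``swim``   anti-phase firing, left offset to the nearest right spike
           close to half the cycle period;
``sync``   in-phase firing, offsets close to zero, one spike per cycle;
``sync2``  double-period synchrony: two spikes per full cycle with
           alternating inter-spike intervals, the near-coincident
           left/right spikes alternately leading and lagging;
``other``  anything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeTrain:
    neuron: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def in_window(self, t_from: float, t_to: float) -> np.ndarray:
        return self.times[(self.times >= t_from) & (self.times <= t_to)]


@dataclass
class AttractorLabel:
    category: str            # rest | swim | sync | sync2 | other
    period: float            # ms, 0 for rest
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ClassificationConfig:
    window: float = 500.0        # analysis window at the trajectory tail, ms
    threshold: float = 0.0       # spike threshold, mV
    epsilon: float = 0.1         # phase tolerance as a fraction of the period
    min_spikes: int = 5          # per side, below which the side counts as silent
    lockout: float = 2.0         # refractory lockout for spike detection, ms

    def __post_init__(self):
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")


# ----------------------------------------------------------------------
# spike detection


def detect_spikes(times: np.ndarray, voltage: np.ndarray,
                  threshold: float = 0.0, lockout: float = 2.0,
                  neuron: str = "") -> SpikeTrain:
    """Upward threshold crossings with a refractory lockout.

    Crossing times are linearly interpolated between samples, so the
    result is robust to the output grid (<= 0.1 ms assumed).
    """
    times = np.asarray(times, dtype=float)
    v = np.asarray(voltage, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    spikes = []
    t_last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        t = times[i] + frac * (times[i + 1] - times[i])
        if t - t_last >= lockout:
            spikes.append(t)
            t_last = t
    return SpikeTrain(neuron=neuron, times=np.asarray(spikes))


def spike_trains(traj, config: ClassificationConfig | None = None) -> dict:
    """Detect spikes of all four neurons of a Trajectory."""
    config = config or ClassificationConfig()
    return {nid: detect_spikes(traj.times, traj.voltage(nid),
                               config.threshold, config.lockout, neuron=nid)
            for nid in ("ldin", "rdin", "lcin", "rcin")}


# ----------------------------------------------------------------------
# period and phase structure


def _alternating_isis(isis: np.ndarray) -> tuple[bool, float]:
    """Detect a two-per-cycle ISI pattern; return (alternating, full period).

    ISIs alternate when even- and odd-indexed intervals form two groups
    whose separation clearly exceeds the within-group spread.
    """
    if len(isis) < 3:
        return False, float(np.median(isis)) if len(isis) else 0.0
    even, odd = isis[0::2], isis[1::2]
    gap = abs(even.mean() - odd.mean())
    spread = even.std() + odd.std()
    mean_isi = isis.mean()
    if gap > 0.08 * mean_isi and gap > 1.5 * spread + 1e-9:
        return True, float(even.mean() + odd.mean())
    return False, float(np.median(isis))


def _signed_offsets(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Signed lag from each left spike to the nearest right spike."""
    if len(left) == 0 or len(right) == 0:
        return np.array([])
    j = np.searchsorted(right, left)
    j0 = np.clip(j - 1, 0, len(right) - 1)
    j1 = np.clip(j, 0, len(right) - 1)
    d0 = right[j0] - left
    d1 = right[j1] - left
    return np.where(np.abs(d0) <= np.abs(d1), d0, d1)


def estimate_period(left: SpikeTrain | np.ndarray, right: SpikeTrain | np.ndarray,
                    window: tuple[float, float] | None = None,
                    min_spikes: int = 5) -> float:
    """Limit-cycle period from the two dIN spike trains (0 = fixed point).

    One spike per cycle gives the median ISI; a two-spikes-per-cycle
    pattern (alternating ISIs) gives the sum of consecutive ISI pairs.
    """
    lt = left.times if isinstance(left, SpikeTrain) else np.asarray(left, float)
    rt = right.times if isinstance(right, SpikeTrain) else np.asarray(right, float)
    if window is not None:
        lt = lt[(lt >= window[0]) & (lt <= window[1])]
        rt = rt[(rt >= window[0]) & (rt <= window[1])]
    if len(lt) < min_spikes or len(rt) < min_spikes:
        return 0.0
    periods = []
    for t in (lt, rt):
        isis = np.diff(t)
        _, T = _alternating_isis(isis)
        periods.append(T)
    return float(np.mean(periods))


def classify_attractor(left: SpikeTrain | np.ndarray,
                       right: SpikeTrain | np.ndarray,
                       config: ClassificationConfig | None = None,
                       window: tuple[float, float] | None = None) -> AttractorLabel:
    """Categorize the tail rhythm of the left/right dIN spike trains."""
    config = config or ClassificationConfig()
    lt = left.times if isinstance(left, SpikeTrain) else np.asarray(left, float)
    rt = right.times if isinstance(right, SpikeTrain) else np.asarray(right, float)
    if window is not None:
        lt = lt[(lt >= window[0]) & (lt <= window[1])]
        rt = rt[(rt >= window[0]) & (rt <= window[1])]

    if len(lt) < config.min_spikes or len(rt) < config.min_spikes:
        return AttractorLabel("rest", 0.0,
                              {"n_left": len(lt), "n_right": len(rt)})

    alt_l, T_l = _alternating_isis(np.diff(lt))
    alt_r, T_r = _alternating_isis(np.diff(rt))
    alternating = alt_l and alt_r
    T = 0.5 * (T_l + T_r)
    if T <= 0:
        return AttractorLabel("other", 0.0, {"reason": "degenerate period"})

    offsets = _signed_offsets(lt, rt)
    # drop edge spikes whose nearest partner may fall outside the window
    if len(offsets) > 2:
        offsets = offsets[1:-1]
    mean_abs = float(np.mean(np.abs(offsets)))
    tol = config.epsilon * T
    isi_ref = 0.5 * T if alternating else T

    diag = {"period": T, "mean_abs_offset": mean_abs,
            "alternating_isis": alternating,
            "isi_cv": float(np.std(np.diff(lt)) / max(np.mean(np.diff(lt)), 1e-12))}

    signs = np.sign(offsets[np.abs(offsets) > 1e-9])
    # fraction of consecutive offset pairs with opposite sign (lead/lag
    # alternation); exactly zero offsets count as trivially alternating
    if len(signs) >= 4:
        alt_frac = float(np.mean(signs[1:] * signs[:-1] < 0))
    else:
        alt_frac = 1.0

    if mean_abs < tol:
        # in-phase firing; a double-period ISI pattern makes it the
        # near-synchronous double cycle rather than plain synchrony
        if alternating:
            return AttractorLabel("sync2", T, diag)
        return AttractorLabel("sync", T, diag)
    if abs(mean_abs - 0.5 * isi_ref) < tol and not alternating:
        # anti-phase: offsets sit at half the firing interval
        return AttractorLabel("swim", T, diag)
    if alternating and alt_frac >= 0.7 and mean_abs < 2.5 * tol:
        # double-period synchrony with a larger lead/lag split
        return AttractorLabel("sync2", T, diag)
    return AttractorLabel("other", T, diag)


def classify_trajectory(traj, config: ClassificationConfig | None = None) -> AttractorLabel:
    """Classify the tail window of a Trajectory from its dIN voltages."""
    config = config or ClassificationConfig()
    t_end = traj.times[-1]
    trains = spike_trains(traj, config)
    return classify_attractor(trains["ldin"], trains["rdin"], config,
                              window=(t_end - config.window, t_end))


# ----------------------------------------------------------------------
# dIN-cIN lag


def cin_din_lag(din: SpikeTrain, cin: SpikeTrain, mode: str = "mean") -> float:
    """Lag of cIN firing behind the preceding same-side dIN spike (ms).

    ``mode='first'`` returns the difference of first spikes only.
    Returns NaN when the cIN never fires.
    """
    if len(cin.times) == 0 or len(din.times) == 0:
        return float("nan")
    if mode == "first":
        return float(cin.times[0] - din.times[0])
    lags = []
    for t in cin.times:
        prior = din.times[din.times <= t]
        if len(prior):
            lags.append(t - prior[-1])
    return float(np.mean(lags)) if lags else float("nan")


# ----------------------------------------------------------------------
# transitions


def window_labels(left: SpikeTrain, right: SpikeTrain, t_end: float,
                  width: float = 100.0, stride: float = 20.0,
                  config: ClassificationConfig | None = None):
    """Sliding-window classification; returns (window centers, labels)."""
    config = config or ClassificationConfig()
    win_cfg = ClassificationConfig(
        window=width, threshold=config.threshold, epsilon=config.epsilon,
        min_spikes=2, lockout=config.lockout)
    centers, labels = [], []
    t0 = 0.0
    while t0 + width <= t_end + 1e-9:
        lab = classify_attractor(left, right, win_cfg, window=(t0, t0 + width))
        centers.append(t0 + 0.5 * width)
        labels.append(lab.category)
        t0 += stride
    return np.asarray(centers), labels


def detect_transition_time(left: SpikeTrain, right: SpikeTrain, t_end: float,
                           width: float = 100.0, stride: float = 20.0,
                           config: ClassificationConfig | None = None) -> float:
    """First time after which the sliding-window label is stably ``swim``.

    Returns 0 when swimming from the first window, and +inf (end-of-run
    marker) when no stable transition to swimming occurs.
    """
    centers, labels = window_labels(left, right, t_end, width, stride, config)
    if not labels:
        return math.inf
    is_swim = np.asarray([lab == "swim" for lab in labels])
    # first window from which everything stays swim
    k = len(is_swim)
    while k > 0 and is_swim[k - 1]:
        k -= 1
    if k == len(is_swim):          # never ends in swimming
        return math.inf
    if k == 0:
        return 0.0
    # midpoint between the last non-swim window and the first stable one
    return float(0.5 * (centers[k - 1] + centers[k]))


# ----------------------------------------------------------------------
# synthetic template generator (classification oracle)


def synthetic_train_pair(category: str, period: float, n_cycles: int,
                         jitter: float, rng: np.random.Generator,
                         t0: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Generate a left/right dIN spike-train pair from a rhythm template.

    ``jitter`` is the half-width of the uniform per-spike time jitter;
    the sync2 template uses a 0.4/0.6 split of the full period and an
    alternating lead of 0.08*period.
    """
    if category == "rest":
        return np.array([]), np.array([])
    base = t0 + period * np.arange(n_cycles)
    if category == "sync":
        left = base
        right = base.copy()
    elif category == "swim":
        left = base
        right = base + 0.5 * period
    elif category == "sync2":
        left = np.sort(np.concatenate([base, base + 0.4 * period]))
        lead = 0.08 * period
        right = left + lead * np.where(np.arange(len(left)) % 2 == 0, 1, -1)
    else:
        raise ValueError(f"unknown template {category!r}")
    left = np.sort(left + rng.uniform(-jitter, jitter, len(left)))
    right = np.sort(right + rng.uniform(-jitter, jitter, len(right)))
    return left, right
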