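"""Deterministic vector field of the reduced tadpole CPG.

The state is a 34-vector split into a left and a right block of 17
variables each::

    block offset + 0..5   dIN  v, m, h, f, l, r
    block offset + 6..10  cIN  v, m, h, f, l
    block offset + 11,12  dIN self-NMDA  o, c
    block offset + 13,14  dIN->cIN AMPA  o, c
    block offset + 15,16  cIN->contralateral-dIN glycine  o, c

The left block occupies indices 0..16 and the right block 17..33, so
the mid-line reflection is the constant permutation exchanging the two
blocks (``swap_sides``); with identical left/right parameters the field
is Z2-equivariant under it.

The hot path is compiled with numba; the module-level functions
(`rate_fn`, `ionic_currents`, ...) are plain-numpy reference
implementations of the individual terms.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import NEURON_IDS, NetworkParams

N_STATE = 34
N_HALF = 17

# per-block state offsets
DIN_V, DIN_M, DIN_H, DIN_F, DIN_L, DIN_R = 0, 1, 2, 3, 4, 5
CIN_V, CIN_M, CIN_H, CIN_F, CIN_L = 6, 7, 8, 9, 10
NMDA_O, NMDA_C = 11, 12
AMPA_O, AMPA_C = 13, 14
GLY_O, GLY_C = 15, 16

#: permutation realizing the mid-line reflection
SWAP_PERM = np.concatenate([np.arange(N_HALF, N_STATE), np.arange(N_HALF)])

#: indices of the four membrane potentials (ldin, rdin, lcin, rcin)
V_INDEX = {"ldin": DIN_V, "rdin": N_HALF + DIN_V,
           "lcin": CIN_V, "rcin": N_HALF + CIN_V}

#: boolean mask of the 30 gating/synaptic variables (everything but voltages)
GATING_MASK = np.ones(N_STATE, dtype=np.bool_)
GATING_MASK[list(V_INDEX.values())] = False

# ----------------------------------------------------------------------
# packed-parameter layout (flat float64 array consumed by the kernels)

_OFF_C = 0
_OFF_CA = 1              # p_ca, F, R, T, ca_in, ca_out
_OFF_NEUR = 7            # 4 neurons x (g_lk, e_lk, g_na, e_na, g_kf, e_kf, g_ks, e_ks)
_OFF_POW = 39            # kf_dIN, ks_dIN, kf_cIN, ks_cIN
_OFF_RATES_DIN = 43      # 5 gates x (alpha ABCDE, beta ABCDE)
_OFF_RATES_CIN = 93      # 4 gates x 10
_OFF_SYN = 133           # 3 kinds (nmda, ampa, gly) x (w, e, tau_o, tau_c, vbar, T, mg)
N_PACKED = 154


def pack_params(p: NetworkParams) -> np.ndarray:
    """Flatten a NetworkParams tree into the kernel parameter vector."""
    p.validate()
    P = np.zeros(N_PACKED)
    P[_OFF_C] = p.C
    ca = p.calcium
    P[_OFF_CA:_OFF_CA + 6] = (ca.p_ca, ca.faraday, ca.gas_constant,
                              ca.temperature_K, ca.ca_in, ca.ca_out)
    for i, nid in enumerate(NEURON_IDS):
        base = p.dIN if nid.endswith("din") else p.cIN
        g = p.conductances_for(nid)
        P[_OFF_NEUR + 8 * i:_OFF_NEUR + 8 * (i + 1)] = (
            g["g_lk"], base.e_lk, g["g_na"], base.e_na,
            g["g_kf"], base.e_kf, g["g_ks"], base.e_ks)
    P[_OFF_POW:_OFF_POW + 4] = (p.dIN.kf_power, p.dIN.ks_power,
                                p.cIN.kf_power, p.cIN.ks_power)
    for j, gate in enumerate(("m", "h", "f", "l", "r")):
        r = p.dIN.rates[gate]
        P[_OFF_RATES_DIN + 10 * j:_OFF_RATES_DIN + 10 * j + 5] = r.alpha
        P[_OFF_RATES_DIN + 10 * j + 5:_OFF_RATES_DIN + 10 * j + 10] = r.beta
    for j, gate in enumerate(("m", "h", "f", "l")):
        r = p.cIN.rates[gate]
        P[_OFF_RATES_CIN + 10 * j:_OFF_RATES_CIN + 10 * j + 5] = r.alpha
        P[_OFF_RATES_CIN + 10 * j + 5:_OFF_RATES_CIN + 10 * j + 10] = r.beta
    weights = {"nmda": p.w_nmda, "ampa": p.w_ampa, "glycine": p.w_inh}
    for j, kind in enumerate(("nmda", "ampa", "glycine")):
        s = p.synapses[kind]
        P[_OFF_SYN + 7 * j:_OFF_SYN + 7 * (j + 1)] = (
            weights[kind], s.e, s.tau_o, s.tau_c, s.vbar, s.T,
            1.0 if s.mg_block else 0.0)
    return P


# ----------------------------------------------------------------------
# scalar building blocks (numba kernels + numpy reference wrappers)


@njit(cache=True, fastmath=False)
def _rate(v, A, B, C, D, E):
    z = (D + v) / E
    if z > 700.0:           # exp overflow -> denominator -> +inf -> rate -> 0
        return 0.0
    if z < -700.0:
        z = -700.0
    return (A + B * v) / (C + math.exp(z))


@njit(cache=True, fastmath=False)
def _mg(v):
    return 1.0 / (1.0 + 0.05 * math.exp(-0.08 * v))


@njit(cache=True, fastmath=False)
def _ghk_ca(v, r, p_ca, F, Rgas, T, ca_in, ca_out):
    """Depolarizing-positive GHK calcium current (pA) for gate value r."""
    mu = 2.0 * F * (v * 1e-3) / (Rgas * T)
    if abs(mu) < 1e-6:
        # analytic v->0 limit of mu*(ca_in - ca_out*exp(-mu))/(1-exp(-mu))
        bracket = (ca_in - ca_out) + 0.5 * mu * (ca_in + ca_out)
    else:
        em = math.exp(-mu)
        bracket = mu * (ca_in - ca_out * em) / (1.0 - em)
    return -2.0 * p_ca * F * bracket * r * r


@njit(cache=True, fastmath=False)
def _transmitter(v_pre, vbar, T):
    x = vbar - v_pre
    if x > 700.0:
        return 0.0
    return T / (1.0 + math.exp(x))


@njit(cache=True, fastmath=False)
def _rhs(y, dy, P, iext):
    """Full 34-dimensional vector field; iext = (ldin, rdin, lcin, rcin) pA."""
    C = P[_OFF_C]
    p_ca = P[_OFF_CA]
    Fc = P[_OFF_CA + 1]
    Rgas = P[_OFF_CA + 2]
    Tk = P[_OFF_CA + 3]
    ca_in = P[_OFF_CA + 4]
    ca_out = P[_OFF_CA + 5]

    w_nmda = P[_OFF_SYN + 0]
    e_nmda = P[_OFF_SYN + 1]
    tau_o_n = P[_OFF_SYN + 2]
    tau_c_n = P[_OFF_SYN + 3]
    vbar_n = P[_OFF_SYN + 4]
    T_n = P[_OFF_SYN + 5]
    mg_n = P[_OFF_SYN + 6]

    w_ampa = P[_OFF_SYN + 7]
    e_ampa = P[_OFF_SYN + 8]
    tau_o_a = P[_OFF_SYN + 9]
    tau_c_a = P[_OFF_SYN + 10]
    vbar_a = P[_OFF_SYN + 11]
    T_a = P[_OFF_SYN + 12]

    w_inh = P[_OFF_SYN + 14]
    e_gly = P[_OFF_SYN + 15]
    tau_o_g = P[_OFF_SYN + 16]
    tau_c_g = P[_OFF_SYN + 17]
    vbar_g = P[_OFF_SYN + 18]
    T_g = P[_OFF_SYN + 19]

    kf_d = P[_OFF_POW]
    ks_d = P[_OFF_POW + 1]
    kf_c = P[_OFF_POW + 2]
    ks_c = P[_OFF_POW + 3]

    for side in range(2):
        s = N_HALF * side
        o = N_HALF * (1 - side)

        # ---------------- dIN ----------------
        nb = _OFF_NEUR + 8 * side          # ldin / rdin conductance block
        v = y[s + DIN_V]
        m = y[s + DIN_M]
        h = y[s + DIN_H]
        f = y[s + DIN_F]
        l = y[s + DIN_L]
        r = y[s + DIN_R]

        i_lk = P[nb] * (P[nb + 1] - v)
        i_na = P[nb + 2] * (P[nb + 3] - v) * m * m * m * h
        i_kf = P[nb + 4] * (P[nb + 5] - v) * f ** kf_d
        i_ks = P[nb + 6] * (P[nb + 7] - v) * l ** ks_d
        i_ca = _ghk_ca(v, r, p_ca, Fc, Rgas, Tk, ca_in, ca_out)

        i_nmda = w_nmda * (e_nmda - v) * (y[s + NMDA_C] - y[s + NMDA_O])
        if mg_n != 0.0:
            i_nmda *= _mg(v)
        i_gly = w_inh * (e_gly - v) * (y[o + GLY_C] - y[o + GLY_O])

        dy[s + DIN_V] = (i_lk + i_na + i_kf + i_ks + i_ca
                         + i_nmda + i_gly + iext[side]) / C

        rb = _OFF_RATES_DIN
        for g in range(5):
            x = y[s + DIN_M + g]
            a = _rate(v, P[rb], P[rb + 1], P[rb + 2], P[rb + 3], P[rb + 4])
            b = _rate(v, P[rb + 5], P[rb + 6], P[rb + 7], P[rb + 8], P[rb + 9])
            dy[s + DIN_M + g] = a * (1.0 - x) - b * x
            rb += 10

        # ---------------- cIN ----------------
        nb = _OFF_NEUR + 8 * (2 + side)    # lcin / rcin conductance block
        vc = y[s + CIN_V]
        mc = y[s + CIN_M]
        hc = y[s + CIN_H]
        fc = y[s + CIN_F]
        lc = y[s + CIN_L]

        i_lk = P[nb] * (P[nb + 1] - vc)
        i_na = P[nb + 2] * (P[nb + 3] - vc) * mc * mc * mc * hc
        i_kf = P[nb + 4] * (P[nb + 5] - vc) * fc ** kf_c
        i_ks = P[nb + 6] * (P[nb + 7] - vc) * lc ** ks_c
        i_ampa = w_ampa * (e_ampa - vc) * (y[s + AMPA_C] - y[s + AMPA_O])

        dy[s + CIN_V] = (i_lk + i_na + i_kf + i_ks + i_ampa + iext[2 + side]) / C

        rb = _OFF_RATES_CIN
        for g in range(4):
            x = y[s + CIN_M + g]
            a = _rate(vc, P[rb], P[rb + 1], P[rb + 2], P[rb + 3], P[rb + 4])
            b = _rate(vc, P[rb + 5], P[rb + 6], P[rb + 7], P[rb + 8], P[rb + 9])
            dy[s + CIN_M + g] = a * (1.0 - x) - b * x
            rb += 10

        # ---------------- synapses ----------------
        # dIN self-NMDA and dIN->cIN AMPA are driven by the same-side dIN,
        # the glycine synapse by the same-side cIN (its current acts on the
        # other side's dIN, handled above through the o-block indices).
        g_n = _transmitter(v, vbar_n, T_n)
        dy[s + NMDA_O] = g_n * (1.0 - y[s + NMDA_O]) - y[s + NMDA_O] / tau_o_n
        dy[s + NMDA_C] = g_n * (1.0 - y[s + NMDA_C]) - y[s + NMDA_C] / tau_c_n

        g_a = _transmitter(v, vbar_a, T_a)
        dy[s + AMPA_O] = g_a * (1.0 - y[s + AMPA_O]) - y[s + AMPA_O] / tau_o_a
        dy[s + AMPA_C] = g_a * (1.0 - y[s + AMPA_C]) - y[s + AMPA_C] / tau_c_a

        g_g = _transmitter(vc, vbar_g, T_g)
        dy[s + GLY_O] = g_g * (1.0 - y[s + GLY_O]) - y[s + GLY_O] / tau_o_g
        dy[s + GLY_C] = g_g * (1.0 - y[s + GLY_C]) - y[s + GLY_C] / tau_c_g


@njit(cache=True, fastmath=False)
def _rhs_half(y, dy, P, iext):
    """17-dimensional restriction to the in-phase manifold y_L = y_R.

    Identical to the left block of the full field except that the
    commissural glycine input to the dIN is read from the same-side
    synapse state (which equals the mirrored one on the manifold).
    iext = (din, cin) pA.
    """
    C = P[_OFF_C]
    p_ca = P[_OFF_CA]
    Fc = P[_OFF_CA + 1]
    Rgas = P[_OFF_CA + 2]
    Tk = P[_OFF_CA + 3]
    ca_in = P[_OFF_CA + 4]
    ca_out = P[_OFF_CA + 5]

    w_nmda = P[_OFF_SYN + 0]
    e_nmda = P[_OFF_SYN + 1]
    tau_o_n = P[_OFF_SYN + 2]
    tau_c_n = P[_OFF_SYN + 3]
    vbar_n = P[_OFF_SYN + 4]
    T_n = P[_OFF_SYN + 5]
    mg_n = P[_OFF_SYN + 6]
    w_ampa = P[_OFF_SYN + 7]
    e_ampa = P[_OFF_SYN + 8]
    tau_o_a = P[_OFF_SYN + 9]
    tau_c_a = P[_OFF_SYN + 10]
    vbar_a = P[_OFF_SYN + 11]
    T_a = P[_OFF_SYN + 12]
    w_inh = P[_OFF_SYN + 14]
    e_gly = P[_OFF_SYN + 15]
    tau_o_g = P[_OFF_SYN + 16]
    tau_c_g = P[_OFF_SYN + 17]
    vbar_g = P[_OFF_SYN + 18]
    T_g = P[_OFF_SYN + 19]

    kf_d = P[_OFF_POW]
    ks_d = P[_OFF_POW + 1]
    kf_c = P[_OFF_POW + 2]
    ks_c = P[_OFF_POW + 3]

    nb = _OFF_NEUR                       # left dIN block
    v = y[DIN_V]
    m = y[DIN_M]
    h = y[DIN_H]
    f = y[DIN_F]
    l = y[DIN_L]
    r = y[DIN_R]
    i_lk = P[nb] * (P[nb + 1] - v)
    i_na = P[nb + 2] * (P[nb + 3] - v) * m * m * m * h
    i_kf = P[nb + 4] * (P[nb + 5] - v) * f ** kf_d
    i_ks = P[nb + 6] * (P[nb + 7] - v) * l ** ks_d
    i_ca = _ghk_ca(v, r, p_ca, Fc, Rgas, Tk, ca_in, ca_out)
    i_nmda = w_nmda * (e_nmda - v) * (y[NMDA_C] - y[NMDA_O])
    if mg_n != 0.0:
        i_nmda *= _mg(v)
    i_gly = w_inh * (e_gly - v) * (y[GLY_C] - y[GLY_O])
    dy[DIN_V] = (i_lk + i_na + i_kf + i_ks + i_ca + i_nmda + i_gly + iext[0]) / C

    rb = _OFF_RATES_DIN
    for g in range(5):
        x = y[DIN_M + g]
        a = _rate(v, P[rb], P[rb + 1], P[rb + 2], P[rb + 3], P[rb + 4])
        b = _rate(v, P[rb + 5], P[rb + 6], P[rb + 7], P[rb + 8], P[rb + 9])
        dy[DIN_M + g] = a * (1.0 - x) - b * x
        rb += 10

    nb = _OFF_NEUR + 16                  # left cIN block
    vc = y[CIN_V]
    mc = y[CIN_M]
    hc = y[CIN_H]
    fc = y[CIN_F]
    lc = y[CIN_L]
    i_lk = P[nb] * (P[nb + 1] - vc)
    i_na = P[nb + 2] * (P[nb + 3] - vc) * mc * mc * mc * hc
    i_kf = P[nb + 4] * (P[nb + 5] - vc) * fc ** kf_c
    i_ks = P[nb + 6] * (P[nb + 7] - vc) * lc ** ks_c
    i_ampa = w_ampa * (e_ampa - vc) * (y[AMPA_C] - y[AMPA_O])
    dy[CIN_V] = (i_lk + i_na + i_kf + i_ks + i_ampa + iext[1]) / C

    rb = _OFF_RATES_CIN
    for g in range(4):
        x = y[CIN_M + g]
        a = _rate(vc, P[rb], P[rb + 1], P[rb + 2], P[rb + 3], P[rb + 4])
        b = _rate(vc, P[rb + 5], P[rb + 6], P[rb + 7], P[rb + 8], P[rb + 9])
        dy[CIN_M + g] = a * (1.0 - x) - b * x
        rb += 10

    g_n = _transmitter(v, vbar_n, T_n)
    dy[NMDA_O] = g_n * (1.0 - y[NMDA_O]) - y[NMDA_O] / tau_o_n
    dy[NMDA_C] = g_n * (1.0 - y[NMDA_C]) - y[NMDA_C] / tau_c_n
    g_a = _transmitter(v, vbar_a, T_a)
    dy[AMPA_O] = g_a * (1.0 - y[AMPA_O]) - y[AMPA_O] / tau_o_a
    dy[AMPA_C] = g_a * (1.0 - y[AMPA_C]) - y[AMPA_C] / tau_c_a
    g_g = _transmitter(vc, vbar_g, T_g)
    dy[GLY_O] = g_g * (1.0 - y[GLY_O]) - y[GLY_O] / tau_o_g
    dy[GLY_C] = g_g * (1.0 - y[GLY_C]) - y[GLY_C] / tau_c_g


# ----------------------------------------------------------------------
# public reference implementations


def rate_fn(v: float, coeffs) -> float:
    """Opening/closing rate (A + B v)/(C + exp((D + v)/E)) in 1/ms.

    Overflow of the exponential saturates the denominator, giving 0.
    """
    A, B, C, D, E = coeffs
    if E == 0:
        raise ValueError("rate coefficient E must be non-zero")
    return _rate(float(v), A, B, C, D, E)


def gating_deriv(x: float, v: float, coeffs) -> float:
    """dx/dt = alpha(v)(1 - x) - beta(v) x for one gating variable."""
    a = rate_fn(v, coeffs.alpha)
    b = rate_fn(v, coeffs.beta)
    return a * (1.0 - x) - b * x


def mg_block(v: float) -> float:
    """Voltage-dependent magnesium unblock of the NMDA receptor."""
    return _mg(float(v))


def transmitter_conc(v_pre: float, s) -> float:
    """Released-transmitter sigmoid T_s/(1 + exp(vbar_s - v_pre))."""
    return _transmitter(float(v_pre), s.vbar, s.T)


def synapse_deriv(y: float, v_pre: float, tau: float, s) -> float:
    """dy/dt = g_s(v_pre)(1 - y) - y/tau for an open/close state variable."""
    return transmitter_conc(v_pre, s) * (1.0 - y) - y / tau


def synaptic_current(v_post: float, o: float, c: float, s, w: float) -> float:
    """i_s = w (e_s - v_post)(c - o), with Mg block applied for NMDA (pA)."""
    i = w * (s.e - v_post) * (c - o)
    if s.mg_block:
        i *= _mg(float(v_post))
    return i


def ghk_current(v: float, r: float, ca) -> float:
    """GHK calcium current in pA (depolarizing positive)."""
    return _ghk_ca(float(v), float(r), ca.p_ca, ca.faraday, ca.gas_constant,
                   ca.temperature_K, ca.ca_in, ca.ca_out)


def ionic_currents(v: float, gating: dict, p, ca=None,
                   conductances: dict | None = None) -> dict:
    """All intrinsic currents of one neuron at (v, gating), in pA.

    ``gating`` maps gate name -> value; ``p`` is a NeuronParams; ``ca``
    the CalciumParams (required when p.calcium). ``conductances`` may
    override the class maximal conductances (symmetry-broken networks).
    """
    g = {k: getattr(p, k) for k in ("g_lk", "g_na", "g_kf", "g_ks")}
    if conductances:
        g.update(conductances)
    out = {
        "i_lk": g["g_lk"] * (p.e_lk - v),
        "i_na": g["g_na"] * (p.e_na - v) * gating["m"] ** 3 * gating["h"],
        "i_kf": g["g_kf"] * (p.e_kf - v) * gating["f"] ** p.kf_power,
        "i_ks": g["g_ks"] * (p.e_ks - v) * gating["l"] ** p.ks_power,
    }
    if p.calcium:
        if ca is None:
            raise ValueError("calcium constants required for a dIN")
        out["i_ca"] = ghk_current(v, gating["r"], ca)
    else:
        out["i_ca"] = 0.0
    return out


def swap_sides(y: np.ndarray) -> np.ndarray:
    """Mid-line reflection: exchange left and right 17-blocks."""
    y = np.asarray(y)
    if y.shape[-1] != N_STATE:
        raise ValueError(f"state must have {N_STATE} components")
    return y[..., SWAP_PERM]


def network_vector_field(t: float, y: np.ndarray, p: NetworkParams | np.ndarray,
                         stim=None) -> np.ndarray:
    """Evaluate the full deterministic field at time t.

    ``p`` may be a NetworkParams or an already-packed parameter vector;
    ``stim`` is anything with an ``external_currents(t) -> 4-vector``
    method (see simulate.InitiationProtocol) or None for no input.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} components")
    P = p if isinstance(p, np.ndarray) else pack_params(p)
    iext = np.zeros(4) if stim is None else np.asarray(stim.external_currents(t))
    dy = np.empty(N_STATE)
    _rhs(y, dy, P, iext)
    return dy


def half_system_vector_field(t: float, y_half: np.ndarray,
                             p: NetworkParams | np.ndarray, stim=None) -> np.ndarray:
    """Evaluate the 17-dimensional in-phase-manifold restriction.

    Refuses symmetry-broken parameters and asymmetric stimuli, for which
    the manifold is not invariant.
    """
    y_half = np.asarray(y_half, dtype=float)
    if y_half.shape != (N_HALF,):
        raise ValueError(f"half state must have {N_HALF} components")
    if isinstance(p, NetworkParams):
        if not p.symmetric:
            raise ValueError("half-system reduction requires symmetric parameters")
        P = pack_params(p)
    else:
        P = p
    if stim is None:
        iext2 = np.zeros(2)
    else:
        i4 = np.asarray(stim.external_currents(t))
        if not (i4[0] == i4[1] and i4[2] == i4[3]):
            raise ValueError("half-system reduction requires a symmetric stimulus")
        iext2 = i4[[0, 2]]
    dy = np.empty(N_HALF)
    _rhs_half(y_half, dy, P, iext2)
    return dy


def embed_half_state(y_half: np.ndarray) -> np.ndarray:
    """Duplicate a 17-state onto the in-phase manifold of the full system."""
    y_half = np.asarray(y_half, dtype=float)
    return np.concatenate([y_half, y_half])
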