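"""Parameter containers for the reduced tadpole CPG network.

The network couples two symmetric half-centres, each containing one
excitatory descending interneuron (dIN) and one inhibitory commissural
interneuron (cIN).  Six graded synapses connect them: each dIN excites
itself through a slow NMDA synapse and its ipsilateral cIN through a
fast AMPA synapse, and each cIN inhibits the contralateral dIN through
a glycinergic synapse.

Unit system: pF, nS, mV, ms -> currents in pA.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

GATE_NAMES_DIN = ("m", "h", "f", "l", "r")
GATE_NAMES_CIN = ("m", "h", "f", "l")
SYNAPSE_KINDS = ("nmda", "ampa", "glycine")

#: neuron instance order used throughout the package
NEURON_IDS = ("ldin", "rdin", "lcin", "rcin")


@dataclass
class RateCoeffs:
    """Five-coefficient opening/closing rate (A + B v)/(C + exp((D + v)/E))."""

    alpha: tuple[float, float, float, float, float]
    beta: tuple[float, float, float, float, float]

    def validate(self, name: str) -> None:
        for kind, coeffs in (("alpha", self.alpha), ("beta", self.beta)):
            if len(coeffs) != 5:
                raise ValueError(f"rate {name}.{kind}: expected 5 coefficients")
            if not all(np.isfinite(c) for c in coeffs):
                raise ValueError(f"rate {name}.{kind}: non-finite coefficient")
            if coeffs[4] == 0.0:
                raise ValueError(f"rate {name}.{kind}: E must be non-zero")


@dataclass
class CalciumParams:
    """Constants of the GHK constant-field calcium current."""

    p_ca: float = 14.25
    faraday: float = 96485.0
    gas_constant: float = 8.314
    temperature_K: float = 300.0
    ca_in: float = 1e-7
    ca_out: float = 1e-5


@dataclass
class NeuronParams:
    """Single-compartment Hodgkin-Huxley neuron of one class (dIN or cIN)."""

    g_lk: float
    e_lk: float
    g_na: float
    e_na: float
    g_kf: float
    e_kf: float
    g_ks: float
    e_ks: float
    kf_power: int
    ks_power: int
    calcium: bool
    rates: dict[str, RateCoeffs]

    def validate(self, name: str) -> None:
        for g in ("g_lk", "g_na", "g_kf", "g_ks"):
            if getattr(self, g) < 0:
                raise ValueError(f"{name}.{g} must be >= 0")
        if self.kf_power < 1 or self.ks_power < 1:
            raise ValueError(f"{name}: gating exponents must be >= 1")
        wanted = GATE_NAMES_DIN if self.calcium else GATE_NAMES_CIN
        for gate in wanted:
            if gate not in self.rates:
                raise ValueError(f"{name}: missing rate table for gate {gate!r}")
            self.rates[gate].validate(f"{name}.{gate}")


@dataclass
class SynapseParams:
    """Graded synapse driven continuously by the presynaptic potential."""

    kind: str
    e: float
    tau_o: float
    tau_c: float
    vbar: float
    T: float
    mg_block: bool

    def validate(self) -> None:
        if self.kind not in SYNAPSE_KINDS:
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if self.tau_o <= 0 or self.tau_c <= 0:
            raise ValueError(f"{self.kind}: synaptic time constants must be > 0")


@dataclass
class NetworkParams:
    """Full parameter tree of the four-neuron network.

    Conductances are stored per neuron *instance* so that the left/right
    symmetry can be broken by perturbing individual maximal conductances
    while channel kinetics stay per class.
    """

    C: float
    calcium: CalciumParams
    dIN: NeuronParams
    cIN: NeuronParams
    synapses: dict[str, SynapseParams]
    w_ampa: float
    w_nmda: float
    w_inh: float
    #: per-instance maximal conductances, overriding the class values;
    #: keys are NEURON_IDS, values map conductance name -> nS.
    conductance_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        self.dIN.validate("dIN")
        self.cIN.validate("cIN")
        if self.cIN.calcium:
            raise ValueError("cIN must have the calcium current disabled")
        for kind in SYNAPSE_KINDS:
            if kind not in self.synapses:
                raise ValueError(f"missing synapse parameters for {kind!r}")
            self.synapses[kind].validate()
        for w in ("w_ampa", "w_nmda", "w_inh"):
            if getattr(self, w) < 0:
                raise ValueError(f"{w} must be >= 0")
        for nid in self.conductance_overrides:
            if nid not in NEURON_IDS:
                raise ValueError(f"unknown neuron id {nid!r} in overrides")

    # ------------------------------------------------------------------
    def copy(self) -> "NetworkParams":
        return copy.deepcopy(self)

    def with_weights(self, w_ampa: float | None = None,
                     w_nmda: float | None = None,
                     w_inh: float | None = None) -> "NetworkParams":
        """Return a copy with some synaptic strengths replaced."""
        p = self.copy()
        if w_ampa is not None:
            p.w_ampa = float(w_ampa)
        if w_nmda is not None:
            p.w_nmda = float(w_nmda)
        if w_inh is not None:
            p.w_inh = float(w_inh)
        return p

    @property
    def symmetric(self) -> bool:
        """True when left and right half-centres have identical parameters."""
        if not self.conductance_overrides:
            return True
        left = {k: v for k, v in self.conductance_overrides.items() if k.startswith("l")}
        right = {k: v for k, v in self.conductance_overrides.items() if k.startswith("r")}
        return {k[1:]: v for k, v in left.items()} == {k[1:]: v for k, v in right.items()}

    def conductances_for(self, neuron_id: str) -> dict[str, float]:
        """Effective maximal conductances of one neuron instance."""
        base = self.dIN if neuron_id.endswith("din") else self.cIN
        out = {g: getattr(base, g) for g in ("g_lk", "g_na", "g_kf", "g_ks")}
        out.update(self.conductance_overrides.get(neuron_id, {}))
        return out


# ----------------------------------------------------------------------
# YAML loading


def _rates_from_dict(d: dict) -> dict[str, RateCoeffs]:
    return {
        gate: RateCoeffs(alpha=tuple(map(float, spec["alpha"])),
                         beta=tuple(map(float, spec["beta"])))
        for gate, spec in d.items()
    }


def _neuron_from_dict(d: dict) -> NeuronParams:
    return NeuronParams(
        g_lk=float(d["g_lk"]), e_lk=float(d["e_lk"]),
        g_na=float(d["g_na"]), e_na=float(d["e_na"]),
        g_kf=float(d["g_kf"]), e_kf=float(d["e_kf"]),
        g_ks=float(d["g_ks"]), e_ks=float(d["e_ks"]),
        kf_power=int(d["kf_power"]), ks_power=int(d["ks_power"]),
        calcium=bool(d["calcium"]),
        rates=_rates_from_dict(d["rates"]),
    )


def params_from_dict(tree: dict) -> NetworkParams:
    ca = tree.get("calcium", {})
    syns = {}
    for kind in SYNAPSE_KINDS:
        s = tree["synapses"][kind]
        syns[kind] = SynapseParams(
            kind=kind, e=float(s["e"]), tau_o=float(s["tau_o"]),
            tau_c=float(s["tau_c"]), vbar=float(s["vbar"]),
            T=float(s["T"]), mg_block=bool(s["mg_block"]),
        )
    p = NetworkParams(
        C=float(tree["membrane_capacitance_pF"]),
        calcium=CalciumParams(
            p_ca=float(ca["p_ca"]), faraday=float(ca["faraday"]),
            gas_constant=float(ca["gas_constant"]),
            temperature_K=float(ca["temperature_K"]),
            ca_in=float(ca["ca_in"]), ca_out=float(ca["ca_out"]),
        ),
        dIN=_neuron_from_dict(tree["neurons"]["dIN"]),
        cIN=_neuron_from_dict(tree["neurons"]["cIN"]),
        synapses=syns,
        w_ampa=float(tree["weights"]["w_ampa"]),
        w_nmda=float(tree["weights"]["w_nmda"]),
        w_inh=float(tree["weights"]["w_inh"]),
    )
    p.validate()
    return p


def params_to_dict(p: NetworkParams) -> dict:
    def neuron(n: NeuronParams) -> dict:
        d = {g: getattr(n, g) for g in
             ("g_lk", "e_lk", "g_na", "e_na", "g_kf", "e_kf", "g_ks", "e_ks")}
        d["kf_power"] = n.kf_power
        d["ks_power"] = n.ks_power
        d["calcium"] = n.calcium
        d["rates"] = {g: {"alpha": list(r.alpha), "beta": list(r.beta)}
                      for g, r in n.rates.items()}
        return d

    return {
        "membrane_capacitance_pF": p.C,
        "calcium": {
            "p_ca": p.calcium.p_ca, "faraday": p.calcium.faraday,
            "gas_constant": p.calcium.gas_constant,
            "temperature_K": p.calcium.temperature_K,
            "ca_in": p.calcium.ca_in, "ca_out": p.calcium.ca_out,
        },
        "neurons": {"dIN": neuron(p.dIN), "cIN": neuron(p.cIN)},
        "synapses": {k: {"e": s.e, "tau_o": s.tau_o, "tau_c": s.tau_c,
                         "vbar": s.vbar, "T": s.T, "mg_block": s.mg_block}
                     for k, s in p.synapses.items()},
        "weights": {"w_ampa": p.w_ampa, "w_nmda": p.w_nmda, "w_inh": p.w_inh},
    }


def load_params(path: str | Path) -> NetworkParams:
    """Load a full NetworkParams tree from a YAML file."""
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def default_params() -> NetworkParams:
    """The packaged default parameter set (Tables of the model definition)."""
    ref = resources.files("tadcpg").joinpath("data/default_params.yaml")
    return params_from_dict(yaml.safe_load(ref.read_text()))
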