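"""Noise-driven transitions from synchrony to swimming.

Starting exactly in phase (delta = 0, A = 0.04 nA) at w_ampa = w_nmda =
10 nS, w_inh = 22.2 nS, the in-phase cycle attracts within the symmetry
manifold but is transversally unstable, so additive noise (phi = 0.01,
Euler-Maruyama dt = 0.01 ms) eventually carries the orbit to swimming
or, occasionally, to rest.  Runs a seeded ensemble of 2-s stochastic
simulations and writes per-replicate outcomes and the transition-time
histogram data to results/05_noise_transitions/.
"""

import sys

import tadcpg as tc
from tadcpg.config import write_results
from tadcpg.experiments import EnsembleSpec, noise_transition_ensemble
from tadcpg.simulate import InitiationProtocol, NoiseSpec

OUT = "results/05_noise_transitions"


def main(n: int = 100, seed: int = 1):
    p = tc.default_params().with_weights(w_ampa=10.0, w_nmda=10.0, w_inh=22.2)
    proto = InitiationProtocol.from_delta(A=0.04, d=6.0, delta=0.0, t1=10.0)
    spec = EnsembleSpec(n=n, base_seed=seed,
                        noise=NoiseSpec(phi=0.01, dt=0.01), duration=2000.0)
    frame = noise_transition_ensemble(p, spec, proto, progress=True)
    counts = frame["outcome"].value_counts().to_dict()
    swim_pct = 100.0 * counts.get("to-swim", 0) / len(frame)
    times = frame.loc[frame["outcome"] == "to-swim", "transition_time"]
    print(f"outcomes over {n} replicates: {counts}")
    print(f"to-swim fraction: {swim_pct:.1f}%")
    print(f"transition times (ms): median {times.median():.0f}, "
          f"range {times.min():.0f}-{times.max():.0f}")
    write_results({"ensemble": frame,
                   "summary": {"n": n, "outcome_counts": counts,
                               "to_swim_percent": swim_pct}}, OUT)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 100
    main(n)
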