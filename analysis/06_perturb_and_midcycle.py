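"""Perturbation-triggered and pulse-triggered rhythm switching.

Two deterministic protocols around the in-phase state: (i) integrate
in-phase to t* = 300 ms, kick every state variable with a Gaussian of
sd 1e-3, and watch the trajectory leave the manifold and settle into
swimming; (ii) establish swimming, then inject a brief step current
(0.45 nA, 5 ms) into the left dIN at the moment of a right-dIN spike to
evoke a near-synchronous bout before swimming resumes.  Writes traces
and window classifications to results/06_perturb_midcycle/.
"""

import tadcpg as tc
from tadcpg.config import write_results
from tadcpg.experiments import midcycle_switch, perturb_and_release
from tadcpg.simulate import InitiationProtocol, PerturbationSpec

OUT = "results/06_perturb_midcycle"


def main(seed: int = 1):
    p = tc.default_params().with_weights(w_ampa=10.0, w_nmda=10.0, w_inh=22.2)
    proto = InitiationProtocol.from_delta(A=0.04, d=6.0, delta=0.0, t1=10.0)
    traj, t_switch = perturb_and_release(
        p, PerturbationSpec(t_star=300.0, sigma=1e-3, seed=seed), proto,
        t_end=2500.0)
    print(f"perturb-and-release: transition to swimming at ~{t_switch:.0f} ms "
          f"(kick at 300 ms)")

    traj2, t_pulse, labels = midcycle_switch(p, t_end=1500.0)
    bout = labels[labels["category"].isin(["sync", "sync2"])]
    print(f"mid-cycle pulse at {t_pulse:.1f} ms; "
          f"{len(bout)} sliding windows classified (double-)synchronous "
          "before swimming resumes")
    write_results({
        "perturb_voltages": traj.voltages_frame(),
        "perturb_transition": {"t_star": 300.0, "sigma": 1e-3,
                               "transition_time": t_switch},
        "midcycle_voltages": traj2.voltages_frame(),
        "midcycle_windows": labels,
        "midcycle_pulse": {"onset": t_pulse, "amplitude_nA": 0.45,
                           "duration_ms": 5.0},
    }, OUT)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
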