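"""Single-cell characterization of the model dIN.

Demonstrates the three signature behaviours of the excitatory
descending interneuron: (i) the resting state and its low firing
threshold, (ii) the depolarized-but-quiescent response to sustained
current with a spike at onset, and (iii) post-inhibitory rebound -- a
spike on release from hyperpolarizing current injected against a
depolarized background.  Writes voltage traces and a summary table to
results/01_single_cell/.
"""

import numpy as np
import pandas as pd

import tadcpg as tc
from tadcpg.config import write_results
from tadcpg.patterns import detect_spikes
from tadcpg.simulate import InitiationProtocol, StimulusEvent, integrate

OUT = "results/01_single_cell"


def main():
    p = tc.default_params().with_weights(w_nmda=0.0)  # bare neuron, no self-excitation
    rest = tc.settle_to_rest(p)
    print(f"dIN resting potential: {rest[0]:.2f} mV; "
          f"cIN resting potential: {rest[6]:.2f} mV")

    # rheobase for a 6 ms pulse
    def fires(A):
        proto = InitiationProtocol.from_delta(A=A, d=6.0, delta=0.0, t1=5.0)
        traj = integrate(rest, p, proto, t_end=120.0, rtol=1e-8, atol=1e-8)
        return len(detect_spikes(traj.times, traj.voltage("ldin")).times) > 0

    lo, hi = 0.001, 0.3
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        lo, hi = (lo, mid) if fires(mid) else (mid, hi)
    print(f"6 ms rheobase: about {hi * 1000:.0f} pA")

    # PIR protocol: depolarizing hold, inhibitory pulse, release
    proto = InitiationProtocol(A=0.0, d=0.0, events=[
        StimulusEvent("ldin", 50.0, 350.0, 0.1),
        StimulusEvent("ldin", 200.0, 60.0, -0.12)])
    traj = integrate(rest, p, proto, t_end=420.0, rtol=1e-9, atol=1e-9)
    spikes = detect_spikes(traj.times, traj.voltage("ldin")).times
    rebound = spikes[(spikes > 260.0) & (spikes < 285.0)]
    print(f"spikes: {np.round(spikes, 1)}")
    print("post-inhibitory rebound spike after release at t=260 ms: "
          f"{'yes, at %.1f ms' % rebound[0] if len(rebound) else 'NOT FOUND'}")

    summary = pd.DataFrame([{
        "rest_din_mV": rest[0], "rest_cin_mV": rest[6],
        "rheobase_6ms_pA": hi * 1000,
        "rebound_spike_ms": rebound[0] if len(rebound) else np.nan,
    }])
    write_results({"pir_trace": traj.voltages_frame(), "summary": summary}, OUT)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
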