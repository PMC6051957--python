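"""Physiological ranges of the pooled excitatory synaptic strengths.

The single modelled AMPA (dIN->cIN) and NMDA (dIN->dIN) synapses stand
in for 15-17 and 13-21 convergent unitary inputs respectively; unitary
maximal conductances are 0.6 nS (AMPA) and 0.15 nS (NMDA, to which the
AMPA unitary is added for the pooled dIN->dIN strength).  Prints and
stores the implied ranges of w_ampa and w_nmda.
"""

from tadcpg.config import write_results
from tadcpg.experiments import physiological_range

OUT = "results/08_physiological_ranges"


def main():
    ampa = physiological_range(15, 17, 0.6)
    nmda = physiological_range(13, 21, 0.6 + 0.15)
    print(f"w_ampa physiological range: ({ampa[0]:g} nS, {ampa[1]:g} nS)")
    print(f"w_nmda physiological range: ({nmda[0]:g} nS, {nmda[1]:g} nS)")
    write_results({"ranges": {"w_ampa_nS": list(ampa),
                              "w_nmda_nS": list(nmda)}}, OUT)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
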