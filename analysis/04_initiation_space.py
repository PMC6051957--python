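"""Initiation-space map: which attractor does each (delta, d) reach?

Covers the rectangle 0 <= delta <= 30 ms, 0 <= d <= 20 ms of the
paired-step initiation protocol (A = 0.01 nA) at three inhibition
strengths, classifying the attractor reached after 3 s.  The grid is
16x16 by default (pass --grid-n for more); the full-resolution map is
the same computation at n=128.  Writes one tidy CSV per w_inh to
results/04_initiation_space/.
"""

import sys

import tadcpg as tc
from tadcpg.config import write_results
from tadcpg.experiments import GridSpec, initiation_space_map

OUT = "results/04_initiation_space"


def main(grid_n: int = 16):
    results = {}
    for w_inh in (28.0, 42.0, 60.0):
        p = tc.default_params().with_weights(w_ampa=10.0, w_nmda=10.0,
                                             w_inh=w_inh)
        grid = GridSpec("delta", (0.0, 30.0), "d", (0.0, 20.0),
                        n1=grid_n, n2=grid_n, duration=3000.0)
        frame = initiation_space_map(p, grid, A=0.01, progress=True)
        counts = frame["category"].value_counts().to_dict()
        print(f"w_inh={w_inh}: {counts}")
        results[f"map_winh{w_inh:g}"] = frame
    write_results(results, OUT)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 16
    main(n)
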