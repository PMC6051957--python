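"""Stability boundaries of swimming and synchrony along w_inh.

Locates, by simulation + bisection at w_ampa = 12 nS, w_nmda = 10 nS:
the inhibition strength below which the anti-phase swimming rhythm is
no longer reached (asymmetric initiation), and the lower boundary of
the sustained in-phase rhythm inside the symmetry manifold (symmetric
initiation).  The transversal (out-of-manifold) upper synchrony
boundary is probed with a near-symmetric initiation; in this
parameterization the in-phase cycle is transversally unstable across
the probed bracket, which the script reports as such.
Writes results/03_boundaries/boundaries.json.
"""

import tadcpg as tc
from tadcpg.config import write_results
from tadcpg.experiments import BoundaryQuery, bisect_stability_boundary
from tadcpg.simulate import InitiationProtocol

OUT = "results/03_boundaries"


def main():
    p = tc.default_params().with_weights(w_ampa=12.0, w_nmda=10.0)
    rest = tc.settle_to_rest(p)
    out = {}

    swim_proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=140.0, t1=10.0)
    b, *_ = bisect_stability_boundary(
        p, BoundaryQuery("w_inh", 3.0, 15.0, "swim", 0.02), swim_proto,
        rest=rest, verbose=True)
    print(f"swimming persistence boundary: w_inh = {b:.2f} nS")
    out["swim_loss_w_inh"] = b

    sync_proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=0.0, t1=10.0)
    try:
        b, *_ = bisect_stability_boundary(
            p, BoundaryQuery("w_inh", 10.0, 22.0, "sync", 0.02), sync_proto,
            rest=rest, verbose=True)
    except ValueError:
        # in-phase rhythm persists below 10 nS here; extend the bracket
        b, *_ = bisect_stability_boundary(
            p, BoundaryQuery("w_inh", 6.0, 22.0, "sync", 0.02), sync_proto,
            rest=rest, verbose=True)
    print(f"in-manifold synchrony floor: w_inh = {b:.2f} nS")
    out["sync_floor_w_inh"] = b

    near_proto = InitiationProtocol.from_delta(A=0.1, d=6.0, delta=1e-4, t1=10.0)
    try:
        b, *_ = bisect_stability_boundary(
            p, BoundaryQuery("w_inh", 22.0, 35.0, "sync", 0.05), near_proto,
            t_end=5000.0, rest=rest, verbose=True)
        out["sync_transversal_upper_w_inh"] = b
        print(f"transversal synchrony upper boundary: w_inh = {b:.2f} nS")
    except ValueError as err:
        out["sync_transversal_upper_w_inh"] = None
        out["sync_transversal_note"] = str(err)
        print(f"transversal synchrony boundary: {err}")

    write_results({"boundaries": out}, OUT)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
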