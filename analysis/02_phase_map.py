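#!/usr/bin/env python
"""Map the steady/jammed phase boundary of the traffic model.

Sweeps the exogenous generation rate lambda on the synthetic funnel
network (mu = 1, K = 10) and classifies each point by the stationarity
of total network contents.  The sweep justifies the operating point
used throughout the synthetic experiments: lambda = 0.05 sits well
inside the steady regime, while rates around unity and above jam the
network until buffers saturate.
"""

from pathlib import Path

from neuroqueue import FunnelSpec, SimParams, make_funnel_network
from neuroqueue.analysis import phase_map

OUT = Path(__file__).resolve().parent.parent / "results"
# global jamming (all buffers full) needs exogenous input comparable to
# per-node service capacity, i.e. lambda of order N; the sweep brackets it
RATES = [0.01, 0.05, 0.2, 1.0, 5.0, 25.0, 120.0, 400.0]


def main(seed: int = 0) -> None:
    net = make_funnel_network(FunnelSpec(seed=seed))
    params = SimParams(
        rate_gen=RATES[0], rate_service=1.0, buffer_capacity=10, duration=4_000.0
    )
    pm = phase_map(net, RATES, params, base_seed=seed)
    frame = pm.to_frame()
    print(frame.to_string(index=False))
    print(f"\ncontents capacity bound N(K+1) = {pm.capacity:.0f}")
    print(f"first jammed rate: {pm.transition_rate()}")

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "phase_map.csv", index=False)
    print(f"wrote {OUT / 'phase_map.csv'}")


if __name__ == "__main__":
    main()
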