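"""Fast vs slow sequence retrieval in the spiking (LIF) network.

The same excitatory/inhibitory network, with Hebbian E->E structure split
into asymmetric and symmetric excitatory halves, retrieves the stored
sequence at different tempos depending only on small (~1 mV) external
bias differences between the two halves.
"""

import numpy as np

from seqspeed import generate_patterns
from seqspeed.spiking import (
    SpikingParams,
    build_spiking_connectivity,
    retrieval_pace,
    simulate_lif,
    sorted_raster,
    spiking_overlaps,
)

p = SpikingParams()
patterns = generate_patterns(16, p.N_E, seed=0)
conn = build_spiking_connectivity(patterns, p, seed=1)

for label, (I_a, I_s), T in [("fast", (0.75, -0.75), 400.0), ("slow", (-1.5, 0.5), 700.0)]:
    spikes, _ = simulate_lif(conn, I_a, I_s, T=T, seed=12, patterns=patterns)
    pace = retrieval_pace(spiking_overlaps(spikes, patterns))
    rate_E = spikes.counts()[spikes.labels != "I"].mean() / (T / 1000.0)
    order = sorted_raster(spikes)
    print(
        f"{label}: biases (I_a, I_s) = ({I_a:+.2f}, {I_s:+.2f}) mV, "
        f"median pace = {pace:.1f} ms/pattern, mean E rate = {rate_E:.1f} Hz"
    )

print(
    "\nBiasing input toward the asymmetric half accelerates the sequence;"
    "\nbiasing toward the symmetric half slows it on identical connectivity."
    "\n(sorted_raster gives the latency ordering used for raster plots.)"
)
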