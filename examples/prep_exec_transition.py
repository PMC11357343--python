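"""Preparatory-period persistence followed by sequence execution.

A brief binarized pattern-1 cue to the symmetric population establishes
persistent activity; strong inhibition of the asymmetric population
holds it for 200 ms (the 'preparatory period'); releasing that
inhibition retrieves the full sequence ('execution'), at a speed set by
the execution inputs.
"""

import numpy as np

from seqspeed import (
    StandardParams,
    make_prep_exec_protocol,
    run_retrieval,
    summarize,
)
from seqspeed.presets import nonlinear_two_pop_network
from seqspeed.protocols_presets import PREP_EXEC_DEFAULTS as D

params = StandardParams(A=20.0, sigma=0.05, theta=0.07)
patterns, conn, _ = nonlinear_two_pop_network(seed=0, params=params)

for label, exec_inputs in [("fast", D["exec_inputs"]), ("slow", D["exec_inputs_slow"])]:
    prot = make_prep_exec_protocol(
        D["prep_duration"],
        D["cue_duration"],
        D["cue_amplitude"],
        D["prep_inputs"],
        exec_inputs,
        cue_binarize_at=D["cue_binarize_at"],
    )
    ov = run_retrieval(
        patterns, conn, params, prot, T=1100.0, single_precision=True, init_mode="zero"
    )
    prep = (ov.times > 30.0) & (ov.times <= D["prep_duration"])
    m1 = np.nanmin(ov.m[0, prep])
    s = summarize(ov, params.tau, burn_in=D["prep_duration"], classify=False)
    print(
        f"{label:4s} execution {exec_inputs}: pattern-1 correlation held >= {m1:.2f} "
        f"during prep; execution speed = {s.speed:.2f}, final-pattern peak = {s.quality:.2f}"
    )

print(
    "\nThe same preparatory state releases into the same sequence at"
    "\ndifferent speeds depending only on the execution-phase inputs."
)
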