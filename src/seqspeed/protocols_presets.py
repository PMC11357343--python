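"""Default input schedules for the preparatory/execution protocol.

During the preparatory period a brief binarized pattern-1 cue to the
symmetric population establishes persistent activity, held by strongly
negative input to the asymmetric population; the execution phase releases
that inhibition and sets the retrieval-speed operating point.  Values are
for the threshold-rule two-population fixture with theta = 0.07,
sigma = 0.05, A = 20; ``exec_inputs_slow`` retrieves the same sequence
about half as fast as the default execution inputs.
"""

PREP_EXEC_DEFAULTS = {
    "prep_duration": 200.0,  # ms
    "cue_duration": 10.0,  # ms
    "cue_amplitude": 1.0,  # binarized pattern-1 cue into the symmetric pop
    "cue_binarize_at": 1.5,
    "prep_inputs": (-2.0, 0.0),  # (I_a, I_s): asymmetric strongly inhibited
    "exec_inputs": (0.0, -0.3),
    "exec_inputs_slow": (0.0, 0.0),
}
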