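"""Reward-driven learning of external inputs for a target retrieval speed.

Starting from inputs (-0.2, -0.2), each trial perturbs the two biases by
lambda * U(-1, 1), runs one retrieval, and keeps the perturbation only
when |v - v_target| improves. The learned inputs are a property of the
network hyperparameters, not of the particular stored sequence.
"""

from seqspeed import (
    LearnerConfig,
    StandardParams,
    learn_inputs,
    measure_speed,
    two_pop_network,
)

params = StandardParams(N=4000, c=0.1, dt=1.0)
patterns, conn, _ = two_pop_network(seed=0, params=params)


def evaluator(I_a, I_s):
    # smooth (soft-exclusion) speed estimate as the reward signal
    s = measure_speed(patterns, conn, params, I_a, I_s, T=800.0, aggregate="soft")
    return s.speed, s.quality


# acceptance slack of one tolerance steps over quenched local optima of
# the desk-scale reward surface (see docs/methods.md)
res = learn_inputs(LearnerConfig(v_target=0.8, seed=1, accept_slack=0.05), evaluator)
print(
    f"converged={res.converged} after {len(res.trials)} trials: "
    f"inputs=({res.inputs[0]:+.2f}, {res.inputs[1]:+.2f}) -> speed {res.speed:.2f}"
)

# transfer: the learned inputs control a freshly stored sequence too
patterns2, conn2, _ = two_pop_network(seed=7, params=params)
s = measure_speed(patterns2, conn2, params, *res.inputs, T=800.0)
print(f"same inputs on a new stored sequence: speed {s.speed:.2f}")
print("\nThe input->speed mapping generalizes across sequences, so it only has to be learned once.")
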