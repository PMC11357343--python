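# seqspeed

Recurrent-network models of **sequence storage with speed-controllable
retrieval**, built on heterogeneous Hebbian plasticity.

Sequential neural activity is observed across motor cortex, hippocampus
and striatum, and its tempo often rescales with behaviour. Classic
temporally *asymmetric* Hebbian rules store a sequence of activity
patterns so that retrieval proceeds at a fixed speed set by the neuronal
time constant. This package implements a generalization in which each
neuron's plasticity mixes a temporally **symmetric** (autoassociative)
and **asymmetric** (sequential) component, with a per-neuron degree of
symmetry `z_i ∈ [0, 1]`:

```
J_ij = (A c_ij)/(N c) [ z_i Σ_{μ=1..P} f(ξ_i^μ) g(ξ_j^μ)
                       + (1 − z_i) Σ_{μ=1..P−1} f(ξ_i^{μ+1}) g(ξ_j^μ) ]
```

for a sequence of `P` i.i.d. standard Gaussian patterns `ξ^μ` over `N`
neurons with structural connectivity `c_ij ~ Bernoulli(c)`. Neurons with
symmetric plasticity act as *brakes* (they stabilize the current
pattern); asymmetric neurons act as *accelerators* (they push toward the
next pattern). Retrieval speed can then be set **dynamically by external
inputs** to the two kinds of neurons, rather than being frozen into the
weights.

The rate dynamics are `τ dr_i/dt = −r_i + φ(Σ_j J_ij r_j + I_i^ext)`
with an erf transfer function; retrieval is read out through pattern
correlations `m_μ(t) = (1/N) Σ_i r_i ξ_i^μ / σ_r(t)` and the speed
`v = τ / ⟨Δt_peaks⟩` (in units of `1/τ`, so `v = 0.5` means one pattern
per `2τ`).

## What is in the package

- `seqspeed.network` — pattern generation, bilinear and threshold
  (binarizing) plasticity rules, homogeneous / bimodal / uniform
  symmetry profiles, sparse connectivity builders (general mixed rule
  and the explicit two-population form).
- `seqspeed.dynamics` — forward-Euler rate integration, per-population
  input protocols, Ornstein–Uhlenbeck input noise, preparatory/execution
  schedules.
- `seqspeed.metrics` — pattern correlations, the peak-interval speed
  estimator with outlier exclusion, retrieval quality, dynamical-regime
  classification (retrieved / persistent / partial-then-persistent).
- `seqspeed.meanfield` — gain functions (quadrature and closed form),
  the speed–symmetry law `v = 1 − z`, two-population overlap ODEs, and
  the retrieval-feasibility condition `max_x [G_a(x) + G_s(x)] ≥ 1`.
- `seqspeed.reward` — perturbation-based reinforcement learning of the
  two external inputs toward a target retrieval speed.
- `seqspeed.spiking` — leaky integrate-and-fire E/I network with
  asymmetric/symmetric excitatory subpopulations and rectified Hebbian
  E→E connectivity.
- `seqspeed.sweep`, `seqspeed.experiments`, `seqspeed.cli` — phase
  diagrams over the input plane, config-driven experiment running, and a
  thin `seqspeed` command-line tool.

## Worked example

```python
import seqspeed as ss

# two-population network: 8000 neurons, 16 stored patterns
patterns, conn, params = ss.two_pop_network(seed=0)

for I_a, I_s in [(0.0, -1.0), (0.0, 0.0)]:
    s = ss.measure_speed(patterns, conn, params, I_a, I_s, T=1200.0)
    print(f"I_a={I_a:+.1f} I_s={I_s:+.1f}  speed={s.speed:.2f}  quality={s.quality:.2f}")
```

prints

```
I_a=+0.0 I_s=-1.0  speed=0.82  quality=0.31
I_a=+0.0 I_s=+0.0  speed=0.44  quality=0.51
```

Silencing the symmetric population (`I_s = −1`) removes the brakes and
retrieval runs at nearly one pattern per `τ`; with equal drive the brakes
engage and the same network retrieves the same sequence at about half
that speed. The quality column is the peak correlation of the final
pattern (success threshold 0.05).

The `examples/` directory contains one short script per capability
(speed vs symmetry, input-plane phase diagram, persistent/sequential
transitions, reward-driven input learning, the spiking network, and the
mean-field gain analysis).

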