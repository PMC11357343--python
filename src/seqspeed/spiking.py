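"""Leaky integrate-and-fire E/I network with asymmetric/symmetric excitatory
subpopulations.

Membrane dynamics (population alpha in {E, I}, voltages in mV, time in ms):

    tau_m dV_i/dt = Theta(V_i - V_floor) * (-V_i + V_rest + I_rec,i(t)
                                            + I_i(t) + sigma sqrt(tau_m) W(t))

with spike threshold/reset, an absolute refractory period, and a voltage
floor that gates the update.  Synapses are delayed exponential filters:
a presynaptic spike of neuron j at t_j^k adds J_ij to the filtered
recurrent input of neuron i at time t_j^k + D, decaying with tau_s.

E->E connectivity is structured by the sequence: patterns are binarized by
the threshold plasticity rule (f for the postsynaptic side, zero-mean g
for the presynaptic side) and imprinted sequentially (mu -> mu+1) on
asymmetric rows and autoassociatively on symmetric rows; in both blocks
the pattern sum runs over mu = 1..P-1.  A rectifying synaptic transfer
omega(x) = max(x, 0) applied to the summed Hebbian term keeps E->E weights
nonnegative; inhibitory weights are nonpositive (Dale's law).  E->I, I->E,
I->I are fixed in-degree random graphs with uniform weights.

Retrieval speed is controlled purely by the external input biases to the
two excitatory subpopulations: biasing the asymmetric population (I_a >
I_s) speeds the sequence up; biasing the symmetric population slows it
down.  The reference slow/fast bias pairs are (I_a, I_s) = (-1.5, +0.5)
and (+0.75, -0.75) mV.

Membrane/synaptic constants and the unstructured-weight scales below are
documented package defaults chosen for a fluctuation-driven regime with
low background rates; all are overridable through :class:`SpikingParams`.
The per-population input scalings lambda_VE and lambda_VI convert the
dimensionless baseline drives into mV; the bias pairs are already in mV
and are added directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .metrics import OverlapTrajectory
from .network import PatternSequence, PlasticityRule

__all__ = [
    "SpikingParams",
    "SpikeData",
    "SpikingConnectivity",
    "build_spiking_connectivity",
    "simulate_lif",
    "smoothed_rates",
    "spiking_overlaps",
    "retrieval_pace",
    "sorted_raster",
]


@dataclass(frozen=True)
class SpikingParams:
    """Parameters of the spiking network (mV, ms)."""

    N_a: int = 1000
    N_s: int = 1000
    N_I: int = 500
    # membrane
    tau_m_E: float = 20.0
    tau_m_I: float = 10.0
    V_rest: float = 0.0
    V_thresh: float = 20.0
    V_reset: float = 0.0
    V_floor: float = 0.0
    tau_rp: float = 2.0
    # synapses
    tau_s_E: float = 5.0  # decay of excitatory synaptic filters
    tau_s_I: float = 3.0
    delay: float = 1.0
    c_EE: float = 0.5  # structural connection probability, E->E block
    K: int = 200  # in-degree of the unstructured blocks
    A_EE: float = 0.25  # Hebbian learning strength (dimensionless)
    w_EE: float = 1800.0  # E->E synaptic conversion scale (mV)
    J_IE: float = 0.3  # E->I weight (mV)
    J_EI: float = -2.0  # I->E weight (mV)
    J_II: float = -1.0
    lambda_VE: float = 5.123  # external-input scaling, E population
    lambda_VI: float = 3.012
    # dimensionless background drives (multiplied by lambda_V into mV)
    # and white-noise amplitudes
    I_base_E: float = 18.0 / 5.123  # lambda_VE * base = 18.0 mV, 2 below threshold
    I_base_I: float = 16.6 / 3.012  # lambda_VI * base = 16.6 mV
    sigma_E: float = 1.5
    sigma_I: float = 1.5
    # plasticity-rule thresholds for pattern binarization
    x_f: float = 1.5
    x_g: float = 1.5
    q_f: float = 0.8

    @property
    def N_E(self) -> int:
        return self.N_a + self.N_s

    @property
    def N(self) -> int:
        return self.N_E + self.N_I


@dataclass
class SpikeData:
    """Spike times per neuron (ms), population labels 'a'/'s'/'I'."""

    spikes: list[np.ndarray]
    labels: np.ndarray
    T: float
    dt: float

    @property
    def N(self) -> int:
        return len(self.spikes)

    def counts(self) -> np.ndarray:
        return np.array([s.size for s in self.spikes])

    def to_table(self) -> np.ndarray:
        """(neuron id, spike time) rows, the two-column text format."""
        rows = [
            np.column_stack([np.full(s.size, i), s])
            for i, s in enumerate(self.spikes)
            if s.size
        ]
        if not rows:
            return np.empty((0, 2))
        return np.concatenate(rows)


@dataclass
class SpikingConnectivity:
    """Full sparse weight matrix; W[i, j] is the synapse j -> i.  Neuron
    order: asymmetric E, symmetric E, inhibitory."""

    W: sp.csr_matrix
    params: SpikingParams
    seed: int


def _fixed_in_degree_block(
    n_post: int, n_pre: int, K: int, weight: float, rng: np.random.Generator
) -> sp.coo_matrix:
    """Each postsynaptic neuron draws exactly K presynaptic partners."""
    K = min(K, n_pre)
    rows = np.repeat(np.arange(n_post), K)
    cols = np.empty(n_post * K, dtype=np.int64)
    for i in range(n_post):
        cols[i * K : (i + 1) * K] = rng.choice(n_pre, size=K, replace=False)
    return sp.coo_matrix(
        (np.full(n_post * K, float(weight)), (rows, cols)), shape=(n_post, n_pre)
    )


def build_spiking_connectivity(
    patterns: PatternSequence,
    params: SpikingParams,
    seed: int,
    rule: Optional[PlasticityRule] = None,
) -> SpikingConnectivity:
    """Build the weight matrix with the rectified Hebbian E->E block:

        J_ij^{aX} = w_EE * c_ij * omega( A_EE / (N_a c) * sum_{mu=1..P-1}
                                         f(xi_i^{mu+1}) g(xi_j^mu) )

    (symmetric rows use f(xi_i^mu) and the 1/(N_s c) normalization).
    ``patterns`` must span the excitatory population.
    """
    p = params
    if patterns.N != p.N_E:
        raise ValueError(f"patterns N={patterns.N} must equal N_E={p.N_E}")
    rule = rule or PlasticityRule.threshold(x_f=p.x_f, x_g=p.x_g, q_f=p.q_f)
    rng = np.random.default_rng(seed)
    F = np.asarray(rule.f(patterns.xi))
    G = np.asarray(rule.g(patterns.xi))
    P = patterns.P

    mask = rng.random((p.N_E, p.N_E)) < p.c_EE
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    is_asym = rows < p.N_a
    hebb = np.zeros(rows.shape[0])
    for mu in range(P - 1):
        g_mu = G[mu, cols]
        hebb += np.where(is_asym, F[mu + 1, rows], F[mu, rows]) * g_mu
    norm = np.where(is_asym, p.N_a, p.N_s) * p.c_EE
    vals = p.w_EE * np.maximum(p.A_EE / norm * hebb, 0.0)
    keep = vals != 0
    W_EE = sp.coo_matrix(
        (vals[keep], (rows[keep], cols[keep])), shape=(p.N_E, p.N_E)
    )

    W_IE = _fixed_in_degree_block(p.N_I, p.N_E, p.K, p.J_IE, rng)
    W_EI = _fixed_in_degree_block(p.N_E, p.N_I, min(p.K, p.N_I), p.J_EI, rng)
    W_II = _fixed_in_degree_block(p.N_I, p.N_I, min(p.K, p.N_I), p.J_II, rng)
    W = sp.bmat([[W_EE, W_EI], [W_IE, W_II]], format="csc")
    return SpikingConnectivity(W=W.tocsr(), params=p, seed=seed)


def simulate_lif(
    conn: SpikingConnectivity,
    I_a: float,
    I_s: float,
    T: float,
    dt: float = 0.1,
    seed: int = 0,
    patterns: Optional[PatternSequence] = None,
    cue_amplitude: float = 6.0,
    cue_duration: float = 20.0,
    record_voltage_of: Optional[np.ndarray] = None,
) -> tuple[SpikeData, Optional[np.ndarray]]:
    """Euler-Maruyama simulation of the LIF network.

    External drive per neuron is lambda_V times the dimensionless
    population base, plus the bias in mV (I_a or I_s for the two
    excitatory subpopulations; inhibitory neurons receive no bias).  When
    ``patterns`` is given, neurons whose first-pattern entry exceeds the
    binarization threshold receive an additional ``cue_amplitude`` (mV)
    for the first ``cue_duration`` ms, initializing the sequence.

    Returns spike times and, optionally, voltage traces of the requested
    neurons.  Raises a numerical-failure error naming the first bad step
    if voltages become non-finite.
    """
    if dt > 0.1 + 1e-12:
        raise ValueError(f"dt must be <= 0.1 ms for the LIF model, got {dt}")
    p = conn.params
    rng = np.random.default_rng(seed)
    N = p.N
    n_steps = int(round(T / dt))
    delay_steps = max(1, int(round(p.delay / dt)))

    tau_m = np.concatenate([np.full(p.N_E, p.tau_m_E), np.full(p.N_I, p.tau_m_I)])
    tau_s = np.concatenate([np.full(p.N_E, p.tau_s_E), np.full(p.N_I, p.tau_s_I)])
    sigma = np.concatenate([np.full(p.N_E, p.sigma_E), np.full(p.N_I, p.sigma_I)])
    drive = np.concatenate(
        [
            np.full(p.N_a, p.lambda_VE * p.I_base_E + I_a),
            np.full(p.N_s, p.lambda_VE * p.I_base_E + I_s),
            np.full(p.N_I, p.lambda_VI * p.I_base_I),
        ]
    )
    cue = np.zeros(N)
    if patterns is not None and cue_amplitude != 0.0:
        cue[: p.N_E] = np.where(patterns.xi[0] >= p.x_f, cue_amplitude, 0.0)

    W = conn.W.tocsc()
    V = p.V_rest + rng.uniform(0.0, 0.5 * (p.V_thresh - p.V_rest), N)
    s_in = np.zeros(N)  # filtered recurrent input (mV)
    refrac_until = np.full(N, -np.inf)
    ring: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(delay_steps)]
    spikes: list[list[float]] = [[] for _ in range(N)]
    labels = np.concatenate(
        [np.full(p.N_a, "a"), np.full(p.N_s, "s"), np.full(p.N_I, "I")]
    )
    vrec = None
    if record_voltage_of is not None:
        vrec = np.empty((n_steps + 1, len(record_voltage_of)))
        vrec[0] = V[record_voltage_of]

    decay_s = np.exp(-dt / tau_s)
    noise_amp = sigma * np.sqrt(dt / tau_m)  # sigma sqrt(tau_m) W(t) term
    for k in range(1, n_steps + 1):
        t = k * dt
        arriving = ring[k % delay_steps]
        if arriving.size:
            s_in += np.asarray(W[:, arriving].sum(axis=1)).ravel()
        I_ext = drive + (cue if t <= cue_duration else 0.0)
        gate = V >= p.V_floor
        dV = (dt / tau_m) * (-V + p.V_rest + s_in + I_ext)
        dV += noise_amp * rng.standard_normal(N)
        V = np.where(gate, V + dV, V)
        s_in *= decay_s
        active = t >= refrac_until
        fired = (V >= p.V_thresh) & active
        V[~active] = p.V_reset
        if np.any(fired):
            idx = np.nonzero(fired)[0]
            for i in idx:
                spikes[i].append(t)
            V[fired] = p.V_reset
            refrac_until[fired] = t + p.tau_rp
            ring[k % delay_steps] = idx
        else:
            ring[k % delay_steps] = np.empty(0, dtype=np.int64)
        if not np.all(np.isfinite(V)):
            raise FloatingPointError(f"non-finite voltages at step {k} (t={t:.2f} ms)")
        if vrec is not None:
            vrec[k] = V[record_voltage_of]

    data = SpikeData(spikes=[np.asarray(s) for s in spikes], labels=labels, T=T, dt=dt)
    return data, vrec


def smoothed_rates(
    spikes: SpikeData, kernel_width: float, dt_grid: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel smoothed firing rates (spikes/ms) on a uniform grid."""
    if kernel_width <= 0:
        raise ValueError("kernel width must be > 0")
    times = np.arange(0.0, spikes.T + dt_grid, dt_grid)
    rates = np.zeros((spikes.N, times.size))
    inv = 1.0 / (kernel_width * np.sqrt(2.0 * np.pi))
    for i, st in enumerate(spikes.spikes):
        if st.size == 0:
            continue
        d = (times[None, :] - st[:, None]) / kernel_width
        rates[i] = inv * np.exp(-0.5 * d * d).sum(axis=0)
    return times, rates


def spiking_overlaps(
    spikes: SpikeData,
    patterns: PatternSequence,
    kernel_width: float = 10.0,
) -> OverlapTrajectory:
    """Pattern correlations of kernel-smoothed excitatory rates.

    Rates are extracted by Gaussian smoothing of the spike trains, then
    correlated with the stored (Gaussian) patterns exactly as in the rate
    model; times with zero rate variance are flagged NaN.
    """
    e_idx = np.nonzero(spikes.labels != "I")[0]
    sub = SpikeData(
        spikes=[spikes.spikes[i] for i in e_idx],
        labels=spikes.labels[e_idx],
        T=spikes.T,
        dt=spikes.dt,
    )
    times, rates = smoothed_rates(sub, kernel_width)
    n = rates.shape[0]
    sd = rates.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = (patterns.xi[:, e_idx] @ rates) / (n * sd[None, :])
    m[:, sd == 0] = np.nan
    return OverlapTrajectory(m=m, times=times, scope="whole")


def retrieval_pace(
    overlaps: OverlapTrajectory, min_amp: float = 0.05
) -> Optional[float]:
    """Median time per pattern (ms) from consecutive correlation peaks.

    Only patterns whose peak correlation reaches ``min_amp`` enter;
    consecutive peak-time differences are normalized by the index gap and
    summarized by the median, which resists spurious peaks of weakly
    tracked patterns.  Returns None when fewer than six patterns are
    tracked.
    """
    filled = np.where(np.isnan(overlaps.m), -np.inf, overlaps.m)
    peaks = overlaps.times[np.argmax(filled, axis=1)]
    amps = np.nanmax(overlaps.m, axis=1)
    mu = np.nonzero(amps >= min_amp)[0]
    if mu.size < 6:
        return None
    d = np.diff(peaks[mu]) / np.diff(mu)
    return float(np.median(d))


def sorted_raster(spikes: SpikeData, kernel_width: float = 10.0) -> np.ndarray:
    """Neuron ordering by the time of peak smoothed firing rate.

    Silent neurons are appended last in index order; simultaneous peaks
    keep a stable index tie-order.
    """
    times, rates = smoothed_rates(spikes, kernel_width)
    active = rates.max(axis=1) > 0
    peak_t = times[np.argmax(rates, axis=1)]
    order_active = np.nonzero(active)[0]
    order_active = order_active[np.argsort(peak_t[active], kind="stable")]
    silent = np.nonzero(~active)[0]
    return np.concatenate([order_active, silent])
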