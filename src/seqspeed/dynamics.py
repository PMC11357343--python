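"""Firing-rate dynamics: transfer function, input protocols, noise, integration.

The network obeys

    tau dr_i/dt = -r_i + phi( sum_j J_ij r_j + I_i^ext(t) )

integrated with forward Euler on a uniform grid.  External input is
specified per population: each neuron receives the mix
``I_i = z_i * I_s + (1 - z_i) * I_a`` of the symmetric- and
asymmetric-population currents, which reduces to a per-population bias for
bimodal z and to a common scalar for homogeneous z.  Currents are
dimensionless, expressed relative to the firing threshold; time is in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import erf

from .network import ConnectivityMatrix, PatternSequence

__all__ = [
    "TransferFunction",
    "Phase",
    "NoiseSpec",
    "InputProtocol",
    "RateTrajectory",
    "constant_protocol",
    "make_prep_exec_protocol",
    "ou_noise",
    "initial_state",
    "integrate",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class TransferFunction:
    """Error-function (sigmoidal) rate transfer phi(h).

    phi(h) = r_max/2 * (1 + erf((h - theta) / (sqrt(2) sigma)))

    ``theta`` is the input at which the neuron fires at half its maximal
    rate, ``sigma`` is inversely proportional to the gain, and ``r_max``
    (default 1: rates as fractions of maximum) bounds the output.
    """

    theta: float = 0.0
    sigma: float = 0.1
    r_max: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.r_max <= 0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")

    def __call__(self, h: np.ndarray | float) -> np.ndarray | float:
        return 0.5 * self.r_max * (1.0 + erf((h - self.theta) / (_SQRT2 * self.sigma)))

    def derivative(self, h: np.ndarray | float) -> np.ndarray | float:
        return (
            self.r_max
            / (np.sqrt(2.0 * np.pi) * self.sigma)
            * np.exp(-((h - self.theta) ** 2) / (2.0 * self.sigma**2))
        )


@dataclass(frozen=True)
class Phase:
    """One interval of an input schedule.  ``t_end=None`` means open-ended.

    ``cue_amplitude`` scales an additive input proportional to a stored
    pattern (``cue_pattern``, 0-based), delivered to ``cue_target``
    ('s', 'a', or 'all').  With ``cue_binarize_at`` set, the cue is the
    binarized pattern (indicator of entries >= the threshold) instead of
    the raw Gaussian pattern — the appropriate cue for threshold-rule
    networks.
    """

    t_start: float
    t_end: Optional[float]
    I_a: float
    I_s: float
    cue_amplitude: float = 0.0
    cue_pattern: int = 0
    cue_target: Literal["s", "a", "all"] = "s"
    cue_binarize_at: Optional[float] = None


@dataclass(frozen=True)
class NoiseSpec:
    """Ornstein-Uhlenbeck input noise, independent across neurons.

    Zero-mean fluctuations with stationary standard deviation ``sd`` and
    correlation time ``tau_corr`` (ms) are added to each neuron's external
    current, so the total input is an OU process around the scheduled bias.
    """

    sd: float = 0.3
    tau_corr: float = 4.0


@dataclass(frozen=True)
class InputProtocol:
    """Ordered, non-overlapping phases covering [0, T), plus optional noise."""

    phases: tuple[Phase, ...]
    noise: Optional[NoiseSpec] = None

    def __post_init__(self):
        t = 0.0
        for ph in self.phases:
            if abs(ph.t_start - t) > 1e-9:
                raise ValueError(
                    f"phase starting at {ph.t_start} ms does not abut previous end {t} ms"
                )
            if ph.t_end is not None and ph.t_end <= ph.t_start:
                raise ValueError("phase must have t_end > t_start")
            t = np.inf if ph.t_end is None else ph.t_end

    def phase_at(self, t: float) -> Phase:
        for ph in self.phases:
            if ph.t_end is None or t < ph.t_end:
                if t >= ph.t_start:
                    return ph
        return self.phases[-1]

    def with_noise(self, noise: Optional[NoiseSpec]) -> "InputProtocol":
        return replace(self, noise=noise)


def constant_protocol(
    I_a: float, I_s: float, noise: Optional[NoiseSpec] = None
) -> InputProtocol:
    """Time-constant per-population biases."""
    return InputProtocol(phases=(Phase(0.0, None, I_a, I_s),), noise=noise)


def make_prep_exec_protocol(
    prep_duration: float,
    cue_duration: float,
    cue_amplitude: float,
    prep_inputs: tuple[float, float],
    exec_inputs: tuple[float, float],
    cue_pattern: int = 0,
    cue_target: str = "s",
    cue_binarize_at: Optional[float] = None,
) -> InputProtocol:
    """Preparatory/execution schedule.

    A brief pattern cue (first ``cue_duration`` ms, delivered to the
    symmetric population by default) establishes a state correlated with
    one stored pattern; ``prep_inputs`` (typically with strongly negative
    asymmetric current) hold it persistently for the rest of the
    ``prep_duration``; ``exec_inputs`` then release the sequence.
    """
    if cue_duration > prep_duration:
        raise ValueError("cue_duration must not exceed prep_duration")
    I_a_p, I_s_p = prep_inputs
    I_a_e, I_s_e = exec_inputs
    phases = [
        Phase(
            0.0,
            cue_duration,
            I_a_p,
            I_s_p,
            cue_amplitude=cue_amplitude,
            cue_pattern=cue_pattern,
            cue_target=cue_target,  # type: ignore[arg-type]
            cue_binarize_at=cue_binarize_at,
        )
    ]
    if prep_duration > cue_duration:
        phases.append(Phase(cue_duration, prep_duration, I_a_p, I_s_p))
    phases.append(Phase(prep_duration, None, I_a_e, I_s_e))
    return InputProtocol(phases=tuple(phases))


def ou_noise(
    mean: float,
    sd: float,
    tau_corr: float,
    dt: float,
    T: float,
    seed: int,
    n: int = 1,
) -> np.ndarray:
    """Exact-discretization Ornstein-Uhlenbeck traces, shape (n, n_steps+1).

    The update x(t+dt) = m + (x - m) e^{-dt/tau_c} + sd sqrt(1 - e^{-2dt/tau_c}) eta
    has exact stationary mean/sd/autocorrelation at any step size; traces
    start from a stationary draw.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if tau_corr <= 0:
        raise ValueError("tau_corr must be > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    out = np.empty((n, n_steps + 1))
    decay = np.exp(-dt / tau_corr)
    diff = sd * np.sqrt(1.0 - decay**2)
    x = mean + sd * rng.standard_normal(n)
    out[:, 0] = x
    for k in range(1, n_steps + 1):
        x = mean + (x - mean) * decay + diff * rng.standard_normal(n)
        out[:, k] = x
    return out


def initial_state(
    patterns: PatternSequence,
    tf: TransferFunction,
    mode: Literal["rate-clamp", "binary-clamp", "zero"] = "rate-clamp",
    x_f: float = 1.5,
) -> np.ndarray:
    """Initial rates matching the first stored pattern.

    ``rate-clamp``: r(0) = phi(xi^1) — the natural initialization for
    bilinear networks.  ``binary-clamp``: r(0) = r_max on the cells whose
    first-pattern entry exceeds the binarization threshold ``x_f``, 0
    elsewhere — the stored-pattern state of threshold-rule networks.
    ``zero``: quiescent start (use a cue-pulse protocol to seed activity).
    """
    if mode == "rate-clamp":
        return np.asarray(tf(patterns.xi[0]))
    if mode == "binary-clamp":
        return np.where(patterns.xi[0] >= x_f, tf.r_max, 0.0)
    if mode == "zero":
        return np.zeros(patterns.N)
    raise ValueError(f"unknown initialization mode: {mode!r}")


@dataclass
class RateTrajectory:
    """Result of integrating the rate equations.

    ``rates`` has shape (n_times, N) or is None when only overlaps were
    recorded.  ``overlaps_raw`` (P, n_times) holds pattern correlations
    computed on the fly when requested (NaN where the rate variance
    vanishes).
    """

    times: np.ndarray
    rates: Optional[np.ndarray]
    dt: float
    tau: float
    seed: int
    overlaps_raw: Optional[np.ndarray] = None
    stopped_early: bool = False


def _neuron_currents(ph: Phase, z: np.ndarray, patterns: Optional[PatternSequence]):
    """Per-neuron baseline current for a phase (bias mix + optional cue)."""
    base = z * ph.I_s + (1.0 - z) * ph.I_a
    if ph.cue_amplitude != 0.0:
        if patterns is None:
            raise ValueError("cue phases require patterns to be supplied")
        xi_cue = patterns.xi[ph.cue_pattern]
        if ph.cue_binarize_at is not None:
            xi_cue = (xi_cue >= ph.cue_binarize_at).astype(float)
        cue = ph.cue_amplitude * xi_cue
        if ph.cue_target == "s":
            cue = np.where(z >= 0.5, cue, 0.0)
        elif ph.cue_target == "a":
            cue = np.where(z < 0.5, cue, 0.0)
        base = base + cue
    return base


def integrate(
    J: ConnectivityMatrix | sp.spmatrix | np.ndarray | None,
    init: np.ndarray,
    protocol: InputProtocol,
    tf: TransferFunction,
    tau: float = 10.0,
    dt: float = 0.5,
    T: float = 500.0,
    seed: int = 0,
    z: Optional[np.ndarray] = None,
    patterns: Optional[PatternSequence] = None,
    record_rates: bool = True,
    record_overlaps: bool = False,
    stop_after_final_peak: bool = False,
    stall_window: Optional[float] = None,
    single_precision: bool = False,
) -> RateTrajectory:
    """Forward-Euler integration of the rate equations.

    Parameters
    ----------
    J
        Recurrent weights (a :class:`ConnectivityMatrix`, any
        scipy-sparse/dense matrix, or None for an unconnected network).
    z
        Per-neuron symmetry degrees for input mixing; taken from ``J``
        when it is a ConnectivityMatrix.
    record_overlaps
        Compute pattern correlations on the fly (requires ``patterns``);
        with ``record_rates=False`` the full rate history is not stored,
        keeping memory at O(N + P*T).
    stop_after_final_peak
        Stop once the final pattern's correlation has peaked and decayed
        (requires overlaps); used by parameter sweeps and trial-based
        learning where only the retrieval summary matters.
    stall_window
        Abort (flagging the run stopped-early) when no new pattern's
        correlation has first crossed 0.15 for this many ms — the sequence
        has died and the remaining integration cannot change the summary.
        Requires overlaps.  Keep None for persistence/attractor protocols.
    single_precision
        Use float32 recurrent weights and rates in the update loop.  The
        matrix-vector product is memory-bound, so this roughly halves the
        step cost; weight entries are O(1e-2) sums of O(K) terms, so the
        relative error is ~1e-6, far below the dynamical noise.

    Raises a configuration error when ``dt > tau/10`` and a numerical
    failure naming the first bad step if rates become non-finite.
    """
    if dt > tau / 10.0 + 1e-12:
        raise ValueError(f"dt={dt} too coarse: require dt <= tau/10 = {tau / 10.0}")
    if isinstance(J, ConnectivityMatrix):
        if z is None:
            z = J.z
        J = J.weights32 if single_precision else J.weights
    if z is None:
        raise ValueError("z profile required (pass z= or a ConnectivityMatrix)")
    if (record_overlaps or stop_after_final_peak or stall_window) and patterns is None:
        raise ValueError("overlap recording requires patterns")

    N = init.shape[0]
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    dtype = np.float32 if single_precision else np.float64
    r = np.asarray(init, dtype=dtype).copy()
    if single_precision and J is not None and J.dtype != np.float32:
        J = J.astype(np.float32)

    rates = np.empty((n_steps + 1, N)) if record_rates else None
    track_overlaps = record_overlaps or stop_after_final_peak or bool(stall_window)
    overlaps = np.full((patterns.P, n_steps + 1), np.nan) if track_overlaps else None

    noise = protocol.noise
    rng = np.random.default_rng(seed)
    if noise is not None and noise.sd > 0:
        eta = noise.sd * rng.standard_normal(N)  # stationary start
        decay = np.exp(-dt / noise.tau_corr)
        diff = noise.sd * np.sqrt(1.0 - decay**2)
    else:
        eta = None

    # rate dispersion below this floor (fraction of r_max) leaves the
    # correlation undefined rather than amplifying numerical noise
    sd_floor = 1e-6 * tf.r_max

    def store(k: int) -> None:
        if rates is not None:
            rates[k] = r
        if overlaps is not None:
            sd_r = r.std()
            if sd_r > sd_floor:
                overlaps[:, k] = (patterns.xi @ r) / (N * sd_r)

    store(0)
    # cache per-phase baseline currents
    phase_cache: dict[int, np.ndarray] = {}
    final_peak = -np.inf
    final_argmax_t = 0.0
    last_k = n_steps
    stopped_early = False
    activation_thresh = 0.15
    activated = np.zeros(patterns.P, dtype=bool) if track_overlaps else None
    last_activation_t = 0.0
    alpha = dtype(dt / tau)
    inv_width = dtype(1.0 / (_SQRT2 * tf.sigma))
    half_rmax = dtype(0.5 * tf.r_max)
    theta = dtype(tf.theta)
    from scipy.special import erf as _erf

    for k in range(1, n_steps + 1):
        t_prev = times[k - 1]
        ph = protocol.phase_at(t_prev)
        key = id(ph)
        if key not in phase_cache:
            phase_cache[key] = _neuron_currents(ph, z, patterns).astype(dtype)
        I = phase_cache[key]
        if eta is not None:
            eta = eta * decay + diff * rng.standard_normal(N)
            I = I + eta.astype(dtype)
        # h -> phi(h) in place: phi = r_max/2 (1 + erf((h - theta)/(sqrt2 sigma)))
        h = J @ r if J is not None else np.zeros(N, dtype=dtype)
        h += I
        h -= theta
        h *= inv_width
        _erf(h, out=h)
        h += dtype(1.0)
        h *= half_rmax
        # forward Euler: r += alpha (phi - r)
        h -= r
        h *= alpha
        r += h
        # flush exponentially decaying rates to exact zero before they
        # reach the subnormal float range, where x86 arithmetic slows by
        # orders of magnitude (silenced populations decay like e^{-t/tau})
        r[r < 1e-12] = 0.0
        if (k & 0xF) == 0 and not np.all(np.isfinite(r)):
            raise FloatingPointError(
                f"non-finite rates at step {k} (t = {times[k]:.3f} ms)"
            )
        store(k)
        if activated is not None and overlaps is not None:
            newly = (overlaps[:, k] >= activation_thresh) & ~activated
            if np.any(newly):
                activated |= newly
                last_activation_t = times[k]
            if (
                stall_window is not None
                and not activated[-1]
                and times[k] - last_activation_t > stall_window
            ):
                last_k = k
                stopped_early = True
                break
        if stop_after_final_peak and overlaps is not None:
            mP = overlaps[-1, k]
            if np.isfinite(mP) and mP > final_peak:
                final_peak = mP
                final_argmax_t = times[k]
            # require a solid final-pattern peak (0.2, well above the 0.05
            # success threshold) so small noise bumps cannot truncate the run
            if (
                final_peak >= 0.2
                and np.isfinite(mP)
                and mP < 0.4 * final_peak
                and times[k] > final_argmax_t + 3.0 * tau
            ):
                last_k = k
                stopped_early = True
                break

    if stopped_early:
        times = times[: last_k + 1]
        if rates is not None:
            rates = rates[: last_k + 1]
        if overlaps is not None:
            overlaps = overlaps[:, : last_k + 1]
    return RateTrajectory(
        times=times,
        rates=rates,
        dt=dt,
        tau=tau,
        seed=seed,
        overlaps_raw=overlaps,
        stopped_early=stopped_early,
    )
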