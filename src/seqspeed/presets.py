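"""Desk-scale standard network fixtures and one-call retrieval runs.

The reference parameter set uses N = 8000 neurons at connection
probability c = 0.05 (mean in-degree N c = 400), P = 16 stored patterns,
tau = 10 ms, Hebbian strength A = 2, transfer threshold theta = 0 and
inverse gain sigma = 0.1.  The in-degree (which sets the crosstalk load
alpha = P/(Nc)) matches the full-scale reference simulations; N = 8000 is
the smallest population whose 1/sqrt(N) overlap noise floor cleanly
supports the slow-retrieval regimes, while keeping builds and runs within
seconds on one CPU.  The nonlinear variant uses the threshold plasticity
rule (x_f = x_g = 1.5, q_f = q_g = 0.8) with A = 20 and sigma = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import (
    InputProtocol,
    NoiseSpec,
    TransferFunction,
    constant_protocol,
    initial_state,
    integrate,
)
from .metrics import OverlapTrajectory, RetrievalSummary, summarize
from .network import (
    ConnectivityMatrix,
    PatternSequence,
    PlasticityRule,
    assign_symmetry,
    build_connectivity,
    build_connectivity_two_pop,
    generate_patterns,
)

__all__ = [
    "StandardParams",
    "standard_params",
    "homogeneous_network",
    "two_pop_network",
    "nonlinear_two_pop_network",
    "run_retrieval",
    "measure_speed",
]


@dataclass(frozen=True)
class StandardParams:
    """Bundle of network + dynamics parameters for the desk-scale fixture."""

    N: int = 8000
    c: float = 0.05
    P: int = 16
    A: float = 2.0
    tau: float = 10.0
    dt: float = 0.5
    theta: float = 0.0
    sigma: float = 0.1
    r_max: float = 1.0

    @property
    def tf(self) -> TransferFunction:
        return TransferFunction(theta=self.theta, sigma=self.sigma, r_max=self.r_max)


def standard_params(**overrides) -> StandardParams:
    return StandardParams(**overrides)


def homogeneous_network(
    z: float,
    seed: int = 0,
    params: Optional[StandardParams] = None,
    rule: Optional[PlasticityRule] = None,
) -> tuple[PatternSequence, ConnectivityMatrix, StandardParams]:
    """Homogeneous-z network (every neuron shares the same symmetry degree)."""
    p = params or StandardParams()
    rule = rule or PlasticityRule.bilinear()
    patterns = generate_patterns(p.P, p.N, seed=seed)
    profile = assign_symmetry(p.N, kind="homogeneous", p=z, seed=seed + 1)
    conn = build_connectivity(patterns, profile, rule, A=p.A, c=p.c, seed=seed + 2)
    return patterns, conn, p


def two_pop_network(
    seed: int = 0,
    params: Optional[StandardParams] = None,
    rule: Optional[PlasticityRule] = None,
) -> tuple[PatternSequence, ConnectivityMatrix, StandardParams]:
    """Two-population (asymmetric/symmetric, equal sizes) bilinear network.

    Built in the per-population normalization (1/(N_a c) for asymmetric
    rows) with unit prefactor, which for equal halves is identical to the
    general mixed rule at strength A = 2.
    """
    p = params or StandardParams()
    rule = rule or PlasticityRule.bilinear()
    patterns = generate_patterns(p.P, p.N, seed=seed)
    conn = build_connectivity_two_pop(
        patterns, rule, A=1.0, c=p.c, N_a=p.N // 2, N_s=p.N - p.N // 2, seed=seed + 2
    )
    return patterns, conn, p


def nonlinear_two_pop_network(
    seed: int = 0,
    params: Optional[StandardParams] = None,
) -> tuple[PatternSequence, ConnectivityMatrix, StandardParams]:
    """Two-population network with the threshold (nonlinear) plasticity rule."""
    p = params or StandardParams(A=20.0, sigma=0.05)
    # q_g is set to the zero-mean solution Phi(1.5) ~ 0.933, keeping the
    # mean connection strength at zero; a nonzero-mean g injects a uniform
    # excitatory background that destroys retrieval at this gain
    rule = PlasticityRule.threshold(x_f=1.5, x_g=1.5, q_f=0.8)
    patterns = generate_patterns(p.P, p.N, seed=seed)
    conn = build_connectivity_two_pop(
        patterns,
        rule,
        A=p.A / 2.0,  # per-population rows; equals the general rule at A
        c=p.c,
        N_a=p.N // 2,
        N_s=p.N - p.N // 2,
        seed=seed + 2,
    )
    return patterns, conn, p


def run_retrieval(
    patterns: PatternSequence,
    conn: ConnectivityMatrix,
    params: StandardParams,
    protocol: InputProtocol,
    T: float = 800.0,
    seed: int = 0,
    stop_after_final_peak: bool = False,
    record_rates: bool = False,
    stall_window: Optional[float] = None,
    single_precision: bool = False,
    init_mode: str = "rate-clamp",
) -> OverlapTrajectory:
    """Initialize to the first pattern, integrate, return whole-network
    overlaps."""
    r0 = initial_state(patterns, params.tf, mode=init_mode)  # type: ignore[arg-type]
    traj = integrate(
        conn,
        r0,
        protocol,
        params.tf,
        tau=params.tau,
        dt=params.dt,
        T=T,
        seed=seed,
        patterns=patterns,
        record_rates=record_rates,
        record_overlaps=True,
        stop_after_final_peak=stop_after_final_peak,
        stall_window=stall_window,
        single_precision=single_precision,
    )
    return OverlapTrajectory(m=traj.overlaps_raw, times=traj.times)


def measure_speed(
    patterns: PatternSequence,
    conn: ConnectivityMatrix,
    params: StandardParams,
    I_a: float,
    I_s: float,
    T: float = 800.0,
    seed: int = 0,
    noise: Optional[NoiseSpec] = None,
    stop_after_final_peak: bool = True,
    classify: bool = False,
    stall_window: Optional[float] = 150.0,
    single_precision: bool = True,
    aggregate: str = "mean",
) -> RetrievalSummary:
    """One-call retrieval run at constant per-population inputs.

    Defaults favour throughput (float32 weights, stall abort after 150 ms
    without a newly activated pattern); pass ``stall_window=None`` and
    ``single_precision=False`` for exact full-length runs.  ``aggregate``
    selects the speed estimator ("mean" with outlier exclusion, the
    reporting convention, or the smooth "median" used as a learning
    reward).
    """
    protocol = constant_protocol(I_a, I_s, noise=noise)
    overlaps = run_retrieval(
        patterns,
        conn,
        params,
        protocol,
        T=T,
        seed=seed,
        stop_after_final_peak=stop_after_final_peak,
        stall_window=stall_window,
        single_precision=single_precision,
    )
    return summarize(overlaps, params.tau, classify=classify, aggregate=aggregate)  # type: ignore[arg-type]
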