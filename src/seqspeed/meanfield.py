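"""Mean-field theory of sequence retrieval.

In the low-load limit the network state is summarized by the overlaps
``q_l`` of the rates with each stored pattern.  Overlap transfer between
consecutive patterns is controlled by the *gain function*

    G(x) = (1/sqrt(x)) Int Dv  v * phi(v sqrt(x) + I),

the Gaussian-averaged slope of the transfer function at input variance
``x`` and mean external input ``I`` (Dv is the standard Gaussian measure).
For the erf transfer with r_max = 1 this has the closed form

    G(x) = 1/sqrt(2 pi (sigma^2 + x)) * exp(-(I - theta)^2 / (2 (sigma^2 + x))).

Headline results housed here:

* homogeneous symmetry degree z — retrieval speed is 1 - z (in 1/tau);
* two-population overlap dynamics (asymmetric drive from pattern l-1,
  symmetric drive from pattern l itself), with a constant-gain reduction
  whose effective time constant is tau / (1 - G_s) and transfer ratio
  G_a / (1 - G_s);
* the retrieval-feasibility condition max_x [G_a(x) + G_s(x)] >= 1 for an
  asymptotically long sequence.

Crosstalk from non-retrieved patterns enters only through supplied noise
amplitudes ``R_l`` (default 0, the low-load limit); their self-consistent
derivation is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate as sp_integrate
from scipy.optimize import minimize_scalar

from .dynamics import TransferFunction

__all__ = [
    "MFTConfig",
    "OverlapState",
    "ConstantGainReduction",
    "gain_integral",
    "gain_closed_form",
    "mft_speed_homogeneous",
    "mft_speed_two_pop",
    "retrieval_feasible",
    "constant_gain_reduction",
    "mft_overlap_dynamics",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def gain_integral(
    x: float,
    theta: float,
    sigma: float,
    I: float,
    r_max: float = 1.0,
) -> float:
    """Gain by direct numerical quadrature of its defining integral.

    Evaluates (1/sqrt(x)) Int Dv v phi(v sqrt(x) + I) adaptively, splitting
    at the transfer transition point so sharp sigmoids (sigma << sqrt(x))
    are resolved.  At x = 0 the integral reduces to phi'(I).
    """
    if x < 0:
        raise ValueError(f"variance x must be >= 0, got {x}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    tf = TransferFunction(theta=theta, sigma=sigma, r_max=r_max)
    if x < 1e-14:
        return float(tf.derivative(I))
    sx = np.sqrt(x)

    def integrand(v: float) -> float:
        return v * tf(v * sx + I) * np.exp(-0.5 * v * v) / _SQRT2PI

    v0 = (theta - I) / sx  # transition of the sigmoid in v
    points = [v0] if -12.0 < v0 < 12.0 else None
    val, _ = sp_integrate.quad(
        integrand, -12.0, 12.0, points=points, limit=200, epsabs=1e-12, epsrel=1e-10
    )
    return float(val / sx)


def gain_closed_form(
    x: float,
    theta: float,
    sigma: float,
    I: float,
    r_max: float = 1.0,
    printed_sign: bool = False,
) -> float:
    """Closed-form gain for the erf transfer.

    Default exponent uses (I - theta)^2, the analytically derived form;
    ``printed_sign=True`` switches to a (theta + I)^2 variant that appears
    in some statements of the formula (the two coincide at theta = 0, the
    setting of all reference phase diagrams).
    """
    if x < 0:
        raise ValueError(f"variance x must be >= 0, got {x}")
    s2 = sigma**2 + x
    num = (theta + I) ** 2 if printed_sign else (I - theta) ** 2
    return float(r_max / np.sqrt(2.0 * np.pi * s2) * np.exp(-num / (2.0 * s2)))


def mft_speed_homogeneous(z: float) -> float:
    """Retrieval speed of the homogeneous-z network: v = 1 - z (units 1/tau).

    At unit gain the overlap cascade obeys tau/(1-z) dq_l/dt = -q_l + q_{l-1},
    a pure sequence clock with period tau/(1-z)."""
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"z must lie in [0, 1], got {z}")
    return 1.0 - z


def _max_gain_sum(theta: float, sigma: float, I_a: float, I_s: float) -> float:
    """max over x >= 0 of G_a(x) + G_s(x), by grid + local refinement."""

    def h(x: float) -> float:
        return gain_closed_form(x, theta, sigma, I_a) + gain_closed_form(
            x, theta, sigma, I_s
        )

    # candidate maximizers: x = 0, the interior optima of each term
    # (sigma^2 + x = (I - theta)^2), and a broad grid
    candidates = [0.0]
    for I in (I_a, I_s):
        x_star = (I - theta) ** 2 - sigma**2
        if x_star > 0:
            candidates.append(x_star)
    x_hi = max(1e3 * sigma**2, *candidates, 1.0)
    grid = np.concatenate([[0.0], np.geomspace(1e-6, x_hi, 60)])
    vals = [h(x) for x in grid]
    best_x = float(grid[int(np.argmax(vals))])
    best = max(vals)
    # local refinement around each candidate
    for x0 in candidates + [best_x]:
        lo = max(0.0, 0.5 * x0 - 1e-6)
        hi = 2.0 * x0 + 1e-3
        res = minimize_scalar(lambda x: -h(x), bounds=(lo, hi), method="bounded")
        if -res.fun > best:
            best = -res.fun
    return float(best)


def retrieval_feasible(
    theta: float, sigma: float, I_a: float, I_s: float
) -> tuple[bool, float]:
    """Whether an asymptotically long sequence is retrievable.

    Returns (feasible, max_x [G_a + G_s]); retrieval requires the maximal
    summed gain to reach one — below it, overlap peaks decay geometrically
    along the sequence.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    m = _max_gain_sum(theta, sigma, I_a, I_s)
    return bool(m >= 1.0 - 1e-12), m


@dataclass(frozen=True)
class ConstantGainReduction:
    """Constant-gain reduction of the combined overlap dynamics:
    tau/(1 - G_s) dq_l/dt = -q_l + G_a/(1 - G_s) q_{l-1}."""

    tau_eff: float  # tau / (1 - G_s)
    transfer_ratio: float  # G_a / (1 - G_s)
    diverging: bool  # G_s >= 1: effective time constant undefined


def constant_gain_reduction(
    G_a: float, G_s: float, tau: float = 10.0
) -> ConstantGainReduction:
    if G_s >= 1.0:
        return ConstantGainReduction(
            tau_eff=float("inf"), transfer_ratio=float("inf"), diverging=True
        )
    return ConstantGainReduction(
        tau_eff=tau / (1.0 - G_s),
        transfer_ratio=G_a / (1.0 - G_s),
        diverging=False,
    )


def mft_speed_two_pop(
    theta: float, sigma: float, I_a: float, I_s: float
) -> Optional[float]:
    """Self-consistent retrieval-speed estimate for the two-population net.

    During stable retrieval the overlap amplitude grows until transfer is
    marginal, G_a(x*) + G_s(x*) = 1 (largest such x*); the constant-gain
    reduction then gives effective time constant tau/(1 - G_s(x*)), i.e.
    speed 1 - G_s(x*) in units of 1/tau.  Returns None when no amplitude
    satisfies the retrieval condition (infeasible inputs).  This is a
    coarse estimate: it ignores crosstalk noise and the rise-phase gain
    excess, and is typically good to ~20%.
    """
    feasible, _ = retrieval_feasible(theta, sigma, I_a, I_s)
    if not feasible:
        return None

    def gsum(x: float) -> float:
        return gain_closed_form(x, theta, sigma, I_a) + gain_closed_form(
            x, theta, sigma, I_s
        )

    # largest root of gsum(x) = 1: scan a log grid from above
    xs = np.geomspace(1e-6, 1e3, 4000)
    vals = np.array([gsum(x) for x in xs])
    above = np.nonzero(vals >= 1.0)[0]
    if above.size == 0:
        return None
    i = above[-1]
    lo, hi = xs[i], xs[min(i + 1, xs.size - 1)]
    for _ in range(80):  # bisection on the decreasing flank
        mid = 0.5 * (lo + hi)
        if gsum(mid) >= 1.0:
            lo = mid
        else:
            hi = mid
    x_star = 0.5 * (lo + hi)
    return 1.0 - gain_closed_form(x_star, theta, sigma, I_s)


@dataclass
class MFTConfig:
    """Parameters of the two-population mean-field overlap dynamics."""

    theta: float = 0.0
    sigma: float = 0.1
    I_a: float = 0.0
    I_s: float = 0.0
    P: int = 16
    tau: float = 10.0
    r_max: float = 1.0
    R_a: float = 0.0  # crosstalk noise amplitude, asymmetric population
    R_s: float = 0.0
    q0: float = 0.4  # initial overlap with pattern 1 (per population)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.R_a < 0 or self.R_s < 0:
            raise ValueError("crosstalk amplitudes R must be >= 0")


@dataclass
class OverlapState:
    """Mean-field overlap trajectories q_l(t) per population, shape (P, nt)."""

    times: np.ndarray
    q_a: np.ndarray
    q_s: np.ndarray

    @property
    def q(self) -> np.ndarray:
        """Combined population overlap q_a + q_s."""
        return self.q_a + self.q_s

    def peak_times(self) -> np.ndarray:
        return self.times[np.argmax(self.q, axis=1)]


def mft_overlap_dynamics(
    config: MFTConfig,
    T: float,
    dt: float = 0.1,
    constant_gains: Optional[tuple[float, float]] = None,
) -> OverlapState:
    """Integrate the coupled two-population overlap ODEs.

    tau dq_a_l/dt = -q_a_l + (q_a_{l-1} + q_s_{l-1}) G_a((q_{l-1})^2 + R_a^2)
    tau dq_s_l/dt = -q_s_l + (q_a_l + q_s_l)         G_s((q_l)^2     + R_s^2)

    Pattern 1 has no predecessor and receives no asymmetric drive; the run
    starts with overlap ``q0`` on pattern 1 in each population.

    ``constant_gains=(G_a, G_s)`` freezes the gains (the linear reduction
    regime): with G_s = 0, G_a = 1 this is the purely asymmetric cascade
    with unit speed (one pattern per tau).
    """
    P = config.P
    n = int(round(T / dt))
    times = np.arange(n + 1) * dt
    qa = np.zeros((P, n + 1))
    qs = np.zeros((P, n + 1))
    qa[0, 0] = config.q0
    qs[0, 0] = config.q0
    a = qa[:, 0].copy()
    s = qs[:, 0].copy()

    if constant_gains is not None:
        ga_const, gs_const = constant_gains

        def Ga(x):
            return ga_const

        def Gs(x):
            return gs_const

    else:

        def Ga(x):
            return gain_closed_form(
                x, config.theta, config.sigma, config.I_a, config.r_max
            )

        def Gs(x):
            return gain_closed_form(
                x, config.theta, config.sigma, config.I_s, config.r_max
            )

    for k in range(1, n + 1):
        q = a + s
        drive_a = np.zeros(P)
        prev = q[:-1]
        drive_a[1:] = prev * np.array([Ga(p * p + config.R_a**2) for p in prev])
        drive_s = q * np.array([Gs(v * v + config.R_s**2) for v in q])
        a = a + dt / config.tau * (-a + drive_a)
        s = s + dt / config.tau * (-s + drive_s)
        qa[:, k] = a
        qs[:, k] = s
    return OverlapState(times=times, q_a=qa, q_s=qs)
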