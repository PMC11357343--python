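"""Pattern generation, plasticity rules, and Hebbian connectivity construction.

A sequence of ``P`` random patterns is imprinted into a sparse recurrent
weight matrix by a Hebbian rule that mixes a temporally *symmetric*
(autoassociative, pattern ``mu`` onto itself) and a temporally *asymmetric*
(sequential, pattern ``mu`` onto ``mu+1``) component.  The per-neuron degree
of temporal symmetry ``z_i`` in [0, 1] interpolates between the two: ``z=1``
is a pure fixed-point (attractor) rule, ``z=0`` a pure sequence rule.  The
mixing depends only on the *postsynaptic* neuron ``i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import scipy.sparse as sp
from scipy.special import ndtr

__all__ = [
    "PatternSequence",
    "PlasticityRule",
    "SymmetryProfile",
    "ConnectivityMatrix",
    "generate_patterns",
    "solve_qg_zero_mean",
    "assign_symmetry",
    "build_connectivity",
    "build_connectivity_two_pop",
]

# Rows of structural masks are drawn in blocks of this many rows to avoid
# dense N x N intermediates for large networks.
_MASK_BLOCK_ROWS = 1024


@dataclass(frozen=True)
class PatternSequence:
    """A sequence of P i.i.d. standard Gaussian patterns over N neurons.

    ``xi[mu, i]`` is the target activation of neuron ``i`` in pattern
    ``mu`` (0-based).  Entries are dimensionless.
    """

    xi: np.ndarray  # shape (P, N)
    seed: int

    @property
    def P(self) -> int:
        return self.xi.shape[0]

    @property
    def N(self) -> int:
        return self.xi.shape[1]

    def subset(self, idx: np.ndarray) -> "PatternSequence":
        """Restrict patterns to a subpopulation of neurons."""
        return PatternSequence(xi=self.xi[:, idx], seed=self.seed)


def generate_patterns(P: int, N: int, seed: int) -> PatternSequence:
    """Draw a sequence of ``P`` i.i.d. standard Gaussian patterns of size ``N``.

    Reproducible: identical ``seed`` gives bitwise-identical entries.
    """
    if P < 2:
        raise ValueError(f"P must be >= 2, got {P}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    xi = rng.standard_normal((P, N))
    return PatternSequence(xi=xi, seed=seed)


@dataclass(frozen=True)
class PlasticityRule:
    """Pre- (g) and postsynaptic (f) factors of the Hebbian rule.

    * ``bilinear``: f(x) = g(x) = x.
    * ``threshold``: f(x) = q_f - 1 + Theta(x - x_f) and likewise for g,
      i.e. patterns are binarized at a threshold.  The step convention is
      Theta(0) = 1 (threshold inclusive).

    For the threshold rule, choosing ``q_g = Phi(x_g)`` (standard normal
    CDF) makes g zero-mean over Gaussian patterns, which keeps the mean
    connection strength at zero; see :func:`solve_qg_zero_mean`.
    """

    kind: Literal["bilinear", "threshold"] = "bilinear"
    x_f: float = 0.0
    x_g: float = 0.0
    q_f: float = 0.0
    q_g: float = 0.0

    def f(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "bilinear":
            return np.asarray(x, dtype=float) if np.ndim(x) else float(x)
        x = np.asarray(x, dtype=float)
        out = self.q_f - 1.0 + (x >= self.x_f).astype(float)
        return out if out.ndim else float(out)

    def g(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "bilinear":
            return np.asarray(x, dtype=float) if np.ndim(x) else float(x)
        x = np.asarray(x, dtype=float)
        out = self.q_g - 1.0 + (x >= self.x_g).astype(float)
        return out if out.ndim else float(out)

    @classmethod
    def bilinear(cls) -> "PlasticityRule":
        return cls(kind="bilinear")

    @classmethod
    def threshold(
        cls,
        x_f: float,
        x_g: float,
        q_f: float,
        q_g: Optional[float] = None,
    ) -> "PlasticityRule":
        """Threshold rule; if ``q_g`` is omitted it is set to the zero-mean
        solution ``Phi(x_g)``."""
        if q_g is None:
            q_g = solve_qg_zero_mean(x_g)
        return cls(kind="threshold", x_f=x_f, x_g=x_g, q_f=q_f, q_g=q_g)


def solve_qg_zero_mean(x_g: float) -> float:
    """Presynaptic offset ``q_g`` enforcing E[g(xi)] = 0 for xi ~ N(0, 1).

    With g(x) = q_g - 1 + Theta(x - x_g), E[g] = q_g - Phi(x_g), so the
    zero-mean solution is the standard normal CDF at the threshold.
    """
    if not np.isfinite(x_g):
        return 1.0 if x_g > 0 else 0.0
    return float(ndtr(x_g))


@dataclass(frozen=True)
class SymmetryProfile:
    """Per-neuron degree of temporal symmetry ``z_i`` in [0, 1]."""

    z: np.ndarray
    kind: Literal["homogeneous", "bimodal", "uniform"]
    p: float
    seed: int

    @property
    def N(self) -> int:
        return self.z.shape[0]

    @property
    def labels(self) -> np.ndarray:
        """Population labels: 's' where z >= 0.5, else 'a'."""
        return np.where(self.z >= 0.5, "s", "a")


def assign_symmetry(
    N: int,
    kind: str = "bimodal",
    p: float = 0.5,
    seed: int = 0,
) -> SymmetryProfile:
    """Draw per-neuron symmetry degrees ``z_i``.

    Parameters
    ----------
    kind
        ``homogeneous`` — all neurons share ``z = p``;
        ``bimodal`` — z_i ~ Bernoulli with P(z_i = 1) = p (two discrete
        populations, symmetric and asymmetric);
        ``uniform`` — z_i ~ U(0, 1) (continuum of rules; ``p`` unused).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    if kind == "homogeneous":
        z = np.full(N, float(p))
    elif kind == "bimodal":
        z = (rng.random(N) < p).astype(float)
    elif kind == "uniform":
        z = rng.random(N)
    else:
        raise ValueError(f"unknown symmetry distribution kind: {kind!r}")
    return SymmetryProfile(z=z, kind=kind, p=p, seed=seed)  # type: ignore[arg-type]


@dataclass
class ConnectivityMatrix:
    """Sparse recurrent weights built by the plasticity rule over a mask.

    ``weights`` is CSR, N x N, with ``weights[i, j]`` the synapse from
    presynaptic ``j`` to postsynaptic ``i``.  ``z`` records the symmetry
    degree of each (postsynaptic) neuron and drives external-input mixing
    downstream.
    """

    weights: sp.csr_matrix
    c: float
    A: float
    z: np.ndarray
    seed: int
    normalization: Literal["global", "per_population"] = "global"
    pop_sizes: Optional[tuple[int, int]] = None  # (N_a, N_s) for two-pop builds

    @property
    def N(self) -> int:
        return self.weights.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return np.where(self.z >= 0.5, "s", "a")

    @property
    def weights32(self) -> sp.csr_matrix:
        """Cached float32 copy of the weights (fast memory-bound matvec)."""
        w32 = getattr(self, "_weights32", None)
        if w32 is None:
            w32 = self.weights.astype(np.float32)
            object.__setattr__(self, "_weights32", w32)
        return w32


def _sparse_mask_indices(N_rows: int, N_cols: int, c: float, rng: np.random.Generator):
    """Row/col indices of Bernoulli(c) structural mask, built in row blocks."""
    rows = []
    cols = []
    for r0 in range(0, N_rows, _MASK_BLOCK_ROWS):
        r1 = min(r0 + _MASK_BLOCK_ROWS, N_rows)
        block = rng.random((r1 - r0, N_cols)) < c
        br, bc = np.nonzero(block)
        rows.append(br + r0)
        cols.append(bc)
    return np.concatenate(rows), np.concatenate(cols)


def _hebbian_values(
    F: np.ndarray,
    G: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    z_rows: np.ndarray,
) -> np.ndarray:
    """Mixed Hebbian sum z_i * sum_mu F[mu,i] G[mu,j] + (1-z_i) * sum_mu F[mu+1,i] G[mu,j]
    evaluated only at the mask's nonzero entries."""
    P = F.shape[0]
    sym = np.zeros(rows.shape[0])
    asym = np.zeros(rows.shape[0])
    for mu in range(P):
        g_mu = G[mu, cols]
        sym += F[mu, rows] * g_mu
        if mu + 1 < P:
            asym += F[mu + 1, rows] * g_mu
    return z_rows * sym + (1.0 - z_rows) * asym


def build_connectivity(
    patterns: PatternSequence,
    profile: SymmetryProfile,
    rule: PlasticityRule,
    A: float,
    c: float,
    seed: int,
    zero_diagonal: bool = True,
) -> ConnectivityMatrix:
    """Build the mixed symmetric/asymmetric Hebbian weight matrix.

    J_ij = A c_ij / (N c) * [ z_i sum_{mu=1..P} f(xi_i^mu) g(xi_j^mu)
                              + (1 - z_i) sum_{mu=1..P-1} f(xi_i^{mu+1}) g(xi_j^mu) ]

    with c_ij ~ Bernoulli(c) i.i.d.  Self-connections are zeroed.
    """
    if not 0.0 < c <= 1.0:
        raise ValueError(f"connection probability c must lie in (0, 1], got {c}")
    if profile.N != patterns.N:
        raise ValueError(
            f"profile has N={profile.N} but patterns have N={patterns.N}"
        )
    N = patterns.N
    rng = np.random.default_rng(seed)
    if c >= 1.0:
        rows, cols = np.divmod(np.arange(N * N), N)
    else:
        rows, cols = _sparse_mask_indices(N, N, c, rng)
    F = np.asarray(rule.f(patterns.xi))
    G = np.asarray(rule.g(patterns.xi))
    vals = _hebbian_values(F, G, rows, cols, profile.z[rows])
    vals *= A / (N * c)
    if zero_diagonal:
        off = rows != cols
        rows, cols, vals = rows[off], cols[off], vals[off]
    J = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    return ConnectivityMatrix(
        weights=J, c=c, A=A, z=profile.z.copy(), seed=seed, normalization="global"
    )


def build_connectivity_two_pop(
    patterns: PatternSequence,
    rule: PlasticityRule,
    A: float,
    c: float,
    N_a: int,
    N_s: int,
    seed: int,
    zero_diagonal: bool = True,
) -> ConnectivityMatrix:
    """Two-population build: the first ``N_a`` neurons are asymmetric, the
    remaining ``N_s`` symmetric.

    Asymmetric rows carry only the sequential term, normalized by N_a c:

        J^{aX}_ij = A c_ij / (N_a c) sum_{mu=1..P-1} f(xi_i^{mu+1}) g(xi_j^mu)

    Symmetric rows carry only the autoassociative term, normalized by N_s c:

        J^{sX}_ij = A c_ij / (N_s c) sum_{mu=1..P}   f(xi_i^mu) g(xi_j^mu)

    Structural masks are i.i.d. Bernoulli(c), drawn independently per block.
    """
    if N_a < 1 or N_s < 1:
        raise ValueError(f"population sizes must be >= 1, got N_a={N_a}, N_s={N_s}")
    if N_a + N_s != patterns.N:
        raise ValueError(
            f"N_a + N_s = {N_a + N_s} does not match patterns N={patterns.N}"
        )
    N = patterns.N
    rng = np.random.default_rng(seed)
    if c >= 1.0:
        rows, cols = np.divmod(np.arange(N * N), N)
    else:
        rows, cols = _sparse_mask_indices(N, N, c, rng)
    F = np.asarray(rule.f(patterns.xi))
    G = np.asarray(rule.g(patterns.xi))
    z = np.concatenate([np.zeros(N_a), np.ones(N_s)])
    vals = _hebbian_values(F, G, rows, cols, z[rows])
    # per-population row normalization: 1/(N_a c) for asymmetric rows,
    # 1/(N_s c) for symmetric rows
    norm = np.where(rows < N_a, N_a, N_s).astype(float) * c
    vals *= A / norm
    if zero_diagonal:
        off = rows != cols
        rows, cols, vals = rows[off], cols[off], vals[off]
    J = sp.csr_matrix((vals, (rows, cols)), shape=(N, N))
    return ConnectivityMatrix(
        weights=J,
        c=c,
        A=A,
        z=z,
        seed=seed,
        normalization="per_population",
        pop_sizes=(N_a, N_s),
    )
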