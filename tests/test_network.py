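"""Network construction: patterns, plasticity rules, connectivity oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate as sp_integrate

from seqspeed import (
    PlasticityRule,
    SymmetryProfile,
    assign_symmetry,
    build_connectivity,
    build_connectivity_two_pop,
    generate_patterns,
    solve_qg_zero_mean,
)


def dense_oracle(xi, z, rule, A, c_mask, c):
    """Brute-force triple loop over (i, j, mu) for the mixed Hebbian rule."""
    P, N = xi.shape
    J = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            s = 0.0
            for mu in range(P):
                s += z[i] * rule.f(xi[mu, i]) * rule.g(xi[mu, j])
                if mu < P - 1:
                    s += (1 - z[i]) * rule.f(xi[mu + 1, i]) * rule.g(xi[mu, j])
            J[i, j] = A * c_mask[i, j] / (N * c) * s
    np.fill_diagonal(J, 0.0)
    return J


class TestPatterns:
    def test_shape_and_reproducibility(self):
        a = generate_patterns(2, 4, seed=5)
        b = generate_patterns(2, 4, seed=5)
        assert a.xi.shape == (2, 4)
        np.testing.assert_array_equal(a.xi, b.xi)

    def test_gaussian_moments(self):
        pats = generate_patterns(8, 100_000, seed=3)
        N = pats.N
        means = pats.xi.mean(axis=1)
        var = pats.xi.var(axis=1)
        assert np.all(np.abs(means) < 4 / np.sqrt(N))
        assert np.all(np.abs(var - 1) < 4 * np.sqrt(2 / N))

    @pytest.mark.parametrize("P,N", [(1, 10), (3, 0), (0, 5)])
    def test_invalid_sizes_raise(self, P, N):
        with pytest.raises(ValueError):
            generate_patterns(P, N, seed=0)


class TestPlasticityRule:
    def test_bilinear_is_identity(self):
        r = PlasticityRule.bilinear()
        assert r.f(2.0) == 2.0
        assert r.g(-0.7) == -0.7

    def test_threshold_evaluation(self):
        # reference nonlinear-rule parameters
        r = PlasticityRule(kind="threshold", x_f=1.5, x_g=1.5, q_f=0.8, q_g=0.8)
        assert r.f(2.0) == pytest.approx(0.8)
        assert r.f(0.0) == pytest.approx(-0.2)
        # step convention: threshold inclusive
        assert r.f(1.5) == pytest.approx(0.8)
        assert r.g(1.5) == pytest.approx(0.8)

    def test_qg_zero_mean_values(self):
        assert solve_qg_zero_mean(0.0) == pytest.approx(0.5)
        assert solve_qg_zero_mean(1.5) == pytest.approx(0.93319, abs=1e-5)
        assert solve_qg_zero_mean(np.inf) == 1.0

    def test_qg_zero_mean_by_quadrature(self):
        """E[g(xi)] vanishes for standard normal xi (independent quadrature)."""
        for x_g in (-0.7, 0.3, 1.5):
            rule = PlasticityRule.threshold(x_f=0.0, x_g=x_g, q_f=0.5)
            val, _ = sp_integrate.quad(
                lambda x: rule.g(x) * np.exp(-x * x / 2) / np.sqrt(2 * np.pi),
                -10,
                10,
                points=[x_g],
            )
            assert abs(val) < 1e-6


class TestSymmetryProfile:
    def test_homogeneous_constant(self):
        prof = assign_symmetry(50, kind="homogeneous", p=0.5, seed=0)
        assert np.all(prof.z == 0.5)

    def test_bimodal_fraction_and_support(self):
        N = 100_000
        prof = assign_symmetry(N, kind="bimodal", p=0.5, seed=1)
        assert set(np.unique(prof.z)) == {0.0, 1.0}
        assert abs(prof.z.mean() - 0.5) < 5 * np.sqrt(0.25 / N)

    def test_uniform_moments(self):
        N = 100_000
        prof = assign_symmetry(N, kind="uniform", seed=2)
        assert abs(prof.z.mean() - 0.5) < 5 * np.sqrt(1 / 12 / N)
        assert abs(prof.z.var() - 1 / 12) < 5e-3
        assert prof.z.min() >= 0 and prof.z.max() <= 1

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            assign_symmetry(10, kind="gamma", seed=0)


class TestConnectivity:
    @pytest.mark.parametrize("kind", ["bilinear", "threshold"])
    @pytest.mark.parametrize("z_const", [0.0, 0.5, 1.0])
    def test_matches_dense_oracle_full_mask(self, small_patterns, kind, z_const):
        """Sparse streaming build equals brute-force evaluation at c=1."""
        if kind == "bilinear":
            rule = PlasticityRule.bilinear()
        else:
            rule = PlasticityRule.threshold(x_f=1.0, x_g=0.5, q_f=0.7)
        prof = SymmetryProfile(
            z=np.full(small_patterns.N, z_const), kind="homogeneous", p=z_const, seed=0
        )
        conn = build_connectivity(small_patterns, prof, rule, A=2.0, c=1.0, seed=4)
        oracle = dense_oracle(
            small_patterns.xi,
            prof.z,
            rule,
            A=2.0,
            c_mask=np.ones((small_patterns.N, small_patterns.N)),
            c=1.0,
        )
        np.testing.assert_allclose(conn.weights.toarray(), oracle, atol=1e-12)

    def test_sparse_matches_oracle_with_mask(self, small_patterns, bilinear_rule):
        """At c<1 the mask drawn by the build is honoured entry-by-entry."""
        prof = assign_symmetry(small_patterns.N, kind="uniform", seed=9)
        conn = build_connectivity(
            small_patterns, prof, bilinear_rule, A=1.3, c=0.4, seed=7
        )
        J = conn.weights.toarray()
        mask = (J != 0).astype(float)
        oracle = dense_oracle(small_patterns.xi, prof.z, bilinear_rule, 1.3, mask, 0.4)
        # oracle uses the realized mask: nonzero entries must agree exactly
        np.testing.assert_allclose(J, oracle * mask, atol=1e-12)

    def test_pure_asymmetric_and_pure_symmetric_limits(self, small_patterns, bilinear_rule):
        xi = small_patterns.xi
        N = small_patterns.N
        prof0 = SymmetryProfile(z=np.zeros(N), kind="homogeneous", p=0.0, seed=0)
        prof1 = SymmetryProfile(z=np.ones(N), kind="homogeneous", p=1.0, seed=0)
        J0 = build_connectivity(small_patterns, prof0, bilinear_rule, 1.0, 1.0, 1).weights.toarray()
        J1 = build_connectivity(small_patterns, prof1, bilinear_rule, 1.0, 1.0, 1).weights.toarray()
        seq = (xi[1:].T @ xi[:-1]) / N
        auto = (xi.T @ xi) / N
        np.fill_diagonal(seq, 0)
        np.fill_diagonal(auto, 0)
        np.testing.assert_allclose(J0, seq, atol=1e-12)
        np.testing.assert_allclose(J1, auto, atol=1e-12)

    def test_mask_density_and_zero_diagonal(self):
        pats = generate_patterns(3, 300, seed=2)
        prof = assign_symmetry(300, kind="homogeneous", p=0.5, seed=0)
        conn = build_connectivity(pats, prof, PlasticityRule.bilinear(), 2.0, 0.1, seed=3)
        J = conn.weights
        assert np.all(J.diagonal() == 0)
        # observed structural density within 5 SE of c (off-diagonal entries)
        n_offdiag = 300 * 299
        density = J.nnz / n_offdiag
        se = np.sqrt(0.1 * 0.9 / n_offdiag)
        # a few stored values cancel exactly with prob ~0 for Gaussians
        assert abs(density - 0.1) < 5 * se

    def test_zero_mean_weights_bilinear(self):
        """E[J_ij] = 0 over pattern draws: empirical mean shrinks as 1/sqrt."""
        pats = generate_patterns(4, 2000, seed=6)
        prof = assign_symmetry(2000, kind="homogeneous", p=0.5, seed=0)
        conn = build_connectivity(pats, prof, PlasticityRule.bilinear(), 2.0, 0.05, seed=8)
        vals = conn.weights.data
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean()) < 5 * se

    def test_determinism(self, small_patterns, bilinear_rule):
        prof = assign_symmetry(small_patterns.N, kind="bimodal", p=0.5, seed=5)
        a = build_connectivity(small_patterns, prof, bilinear_rule, 2.0, 0.5, seed=12)
        b = build_connectivity(small_patterns, prof, bilinear_rule, 2.0, 0.5, seed=12)
        assert (a.weights != b.weights).nnz == 0

    def test_mismatched_sizes_raise(self, small_patterns, bilinear_rule):
        prof = assign_symmetry(small_patterns.N + 1, kind="homogeneous", p=0.5, seed=0)
        with pytest.raises(ValueError):
            build_connectivity(small_patterns, prof, bilinear_rule, 1.0, 0.5, seed=0)


class TestTwoPopulationBuild:
    def test_equivalence_to_general_rule(self, small_patterns, bilinear_rule):
        """Printed per-population normalization (unit prefactor) equals the
        general mixed rule at A=2 for equal halves (c=1: no mask noise)."""
        N = small_patterns.N
        z = np.concatenate([np.zeros(N // 2), np.ones(N - N // 2)])
        prof = SymmetryProfile(z=z, kind="bimodal", p=0.5, seed=0)
        two = build_connectivity_two_pop(
            small_patterns, bilinear_rule, A=1.0, c=1.0, N_a=N // 2, N_s=N - N // 2, seed=1
        )
        gen = build_connectivity(small_patterns, prof, bilinear_rule, A=2.0, c=1.0, seed=1)
        np.testing.assert_allclose(two.weights.toarray(), gen.weights.toarray(), atol=1e-12)

    def test_block_structure(self, small_patterns, bilinear_rule):
        """Asymmetric rows carry only mu->mu+1 terms, symmetric rows only
        mu->mu terms."""
        N = small_patterns.N
        xi = small_patterns.xi
        N_a = N // 2
        conn = build_connectivity_two_pop(
            small_patterns, bilinear_rule, A=1.0, c=1.0, N_a=N_a, N_s=N - N_a, seed=1
        )
        J = conn.weights.toarray()
        seq = xi[1:].T @ xi[:-1] / (N_a * 1.0)
        auto = xi.T @ xi / ((N - N_a) * 1.0)
        np.testing.assert_allclose(J[:N_a], np.where(np.eye(N)[:N_a] > 0, 0, seq[:N_a]), atol=1e-12)
        np.testing.assert_allclose(
            J[N_a:], np.where(np.eye(N)[N_a:] > 0, 0, auto[N_a:]), atol=1e-12
        )

    def test_single_pattern_asym_block_empty(self):
        """P=1 leaves the sequential (mu -> mu+1) sum empty: asymmetric
        rows are all-zero while symmetric rows are not."""
        from seqspeed import PatternSequence

        rng = np.random.default_rng(0)
        pats1 = PatternSequence(xi=rng.standard_normal((1, 10)), seed=0)
        conn = build_connectivity_two_pop(
            pats1, PlasticityRule.bilinear(), A=1.0, c=1.0, N_a=5, N_s=5, seed=1
        )
        J = conn.weights.toarray()
        assert np.allclose(J[:5], 0.0)
        assert np.abs(J[5:]).sum() > 0

    def test_zero_population_raises(self, small_patterns, bilinear_rule):
        with pytest.raises(ValueError):
            build_connectivity_two_pop(
                small_patterns, bilinear_rule, 1.0, 0.5, N_a=0, N_s=small_patterns.N, seed=0
            )


@settings(max_examples=20, deadline=None)
@given(
    z=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**20),
)
def test_connectivity_oracle_property(z, seed):
    """Random small instances always match the dense brute-force build."""
    pats = generate_patterns(3, 12, seed=seed)
    prof = SymmetryProfile(z=np.full(12, z), kind="homogeneous", p=z, seed=0)
    rule = PlasticityRule.bilinear()
    conn = build_connectivity(pats, prof, rule, A=1.7, c=1.0, seed=seed)
    oracle = dense_oracle(pats.xi, prof.z, rule, 1.7, np.ones((12, 12)), 1.0)
    np.testing.assert_allclose(conn.weights.toarray(), oracle, atol=1e-10)
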