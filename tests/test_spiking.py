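"""Spiking (LIF) network: connectivity, simulation mechanics, overlaps,
raster ordering.  The fast-vs-slow retrieval ordering is covered by the
acceptance suite."""

import numpy as np
import pytest

from seqspeed import PatternSequence, generate_patterns
from seqspeed.spiking import (
    SpikeData,
    SpikingParams,
    build_spiking_connectivity,
    simulate_lif,
    smoothed_rates,
    sorted_raster,
    spiking_overlaps,
)


@pytest.fixture(scope="module")
def tiny_params():
    return SpikingParams(N_a=60, N_s=60, N_I=30, K=20)


class TestSpikingConnectivity:
    def test_dense_brute_force_small_instance(self):
        """E->E block equals a per-entry loop evaluation of the rectified
        Hebbian rule (structural mask honoured)."""
        p = SpikingParams(N_a=20, N_s=20, N_I=10, K=5, c_EE=1.0)
        pats = generate_patterns(3, p.N_E, seed=3)
        conn = build_spiking_connectivity(pats, p, seed=4)
        from seqspeed import PlasticityRule

        rule = PlasticityRule.threshold(x_f=p.x_f, x_g=p.x_g, q_f=p.q_f)
        W = conn.W.toarray()[: p.N_E, : p.N_E]
        for i in range(p.N_E):
            for j in range(p.N_E):
                if i == j:
                    assert W[i, j] == 0.0
                    continue
                s = 0.0
                for mu in range(pats.P - 1):
                    fi = rule.f(pats.xi[mu + 1, i]) if i < p.N_a else rule.f(pats.xi[mu, i])
                    s += fi * rule.g(pats.xi[mu, j])
                n_x = p.N_a if i < p.N_a else p.N_s
                expected = p.w_EE * max(p.A_EE / (n_x * p.c_EE) * s, 0.0)
                assert W[i, j] == pytest.approx(expected, abs=1e-10)

    def test_dales_law(self, tiny_params):
        pats = generate_patterns(4, tiny_params.N_E, seed=0)
        conn = build_spiking_connectivity(pats, tiny_params, seed=1)
        W = conn.W.tocsc()
        N_E = tiny_params.N_E
        assert W[:, :N_E].min() >= 0.0  # excitatory columns nonnegative
        assert W[:, N_E:].max() <= 0.0  # inhibitory columns nonpositive

    def test_zero_learning_strength_removes_structure(self, tiny_params):
        from dataclasses import replace

        p = replace(tiny_params, A_EE=0.0)
        pats = generate_patterns(4, p.N_E, seed=0)
        conn = build_spiking_connectivity(pats, p, seed=1)
        assert abs(conn.W.tocsr()[: p.N_E, : p.N_E]).sum() == 0.0


class TestSimulation:
    def test_subthreshold_relaxation_no_spikes(self, tiny_params):
        """Zero weights, subthreshold drive, no noise: V -> rest + drive."""
        from dataclasses import replace

        p = replace(tiny_params, sigma_E=0.0, sigma_I=0.0, I_base_E=2.0, I_base_I=2.0)
        pats = generate_patterns(3, p.N_E, seed=0)
        conn = build_spiking_connectivity(pats, p, seed=1)
        conn.W.data[:] = 0.0
        spk, vrec = simulate_lif(
            conn, 0.0, 0.0, T=150.0, seed=2, record_voltage_of=np.arange(3),
            patterns=None, cue_amplitude=0.0,
        )
        assert spk.counts().sum() == 0
        target = p.lambda_VE * 2.0
        assert vrec[-1, 0] == pytest.approx(target, abs=0.05)

    def test_refractory_period_enforced(self, tiny_params):
        from dataclasses import replace

        p = replace(tiny_params, I_base_E=5.0)  # strong suprathreshold drive
        pats = generate_patterns(3, p.N_E, seed=0)
        conn = build_spiking_connectivity(pats, p, seed=1)
        spk, _ = simulate_lif(conn, 1.0, 1.0, T=100.0, seed=3, patterns=pats)
        assert spk.counts().sum() > 0
        for st in spk.spikes:
            if st.size > 1:
                assert np.all(np.diff(st) >= p.tau_rp - 1e-9)

    def test_seeded_determinism(self, tiny_params):
        pats = generate_patterns(3, tiny_params.N_E, seed=0)
        conn = build_spiking_connectivity(pats, tiny_params, seed=1)
        a, _ = simulate_lif(conn, 0.5, -0.5, T=80.0, seed=9, patterns=pats)
        b, _ = simulate_lif(conn, 0.5, -0.5, T=80.0, seed=9, patterns=pats)
        for x, y in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(x, y)

    def test_coarse_dt_rejected(self, tiny_params):
        pats = generate_patterns(3, tiny_params.N_E, seed=0)
        conn = build_spiking_connectivity(pats, tiny_params, seed=1)
        with pytest.raises(ValueError):
            simulate_lif(conn, 0.0, 0.0, T=10.0, dt=0.5)


class TestSpikingOverlaps:
    def test_pattern_proportional_poisson_rates(self):
        """Poisson spiking at rates tied to one binarized pattern produces a
        correlation near the analytic value for that pattern."""
        rng = np.random.default_rng(5)
        N = 1500
        pats = generate_patterns(3, N, seed=6)
        active = pats.xi[1] >= 1.5
        rates_hz = np.where(active, 80.0, 2.0)
        T = 400.0
        spikes = []
        for lam in rates_hz:
            n = rng.poisson(lam * T / 1000.0)
            spikes.append(np.sort(rng.uniform(0, T, n)))
        spk = SpikeData(spikes=spikes, labels=np.full(N, "a"), T=T, dt=0.1)
        w = 10.0
        ov = spiking_overlaps(spk, pats, kernel_width=w)
        # analytic correlation of the construction: covariance of the rate
        # profile with the pattern, over the total dispersion = rate
        # heterogeneity plus Poisson shot noise of the kernel estimator
        # (variance lambda * int k^2 = lambda / (2 sqrt(pi) w))
        r = np.where(active, 0.080, 0.002)  # spikes/ms
        shot = r.mean() / (2 * np.sqrt(np.pi) * w)
        expected = (r * pats.xi[1]).mean() / np.sqrt(r.var() + shot)
        mid = ov.m[1, ov.times > 50.0]
        assert np.nanmean(mid) == pytest.approx(expected, rel=0.1)

    def test_no_spikes_flagged_undefined(self):
        spk = SpikeData(
            spikes=[np.array([]) for _ in range(10)],
            labels=np.full(10, "a"),
            T=50.0,
            dt=0.1,
        )
        pats = generate_patterns(2, 10, seed=0)
        ov = spiking_overlaps(spk, pats)
        assert np.all(np.isnan(ov.m))


class TestSortedRaster:
    def _burst(self, center, n=5, rate_n=30):
        return np.sort(np.random.default_rng(int(center)).uniform(center - 5, center + 5, rate_n))

    def test_recovers_construction_order(self):
        order_true = [30.0, 60.0, 90.0, 120.0]
        spikes = [self._burst(c) for c in order_true]
        spk = SpikeData(spikes=spikes, labels=np.full(4, "a"), T=150.0, dt=0.1)
        np.testing.assert_array_equal(sorted_raster(spk), np.arange(4))

    def test_silent_neurons_appended_last(self):
        spikes = [self._burst(80.0), np.array([]), self._burst(40.0), np.array([])]
        spk = SpikeData(spikes=spikes, labels=np.full(4, "a"), T=150.0, dt=0.1)
        np.testing.assert_array_equal(sorted_raster(spk), [2, 0, 1, 3])

    def test_simultaneous_bursts_stable_tie_order(self):
        spikes = [np.array([50.0, 51.0])] * 3
        spk = SpikeData(spikes=spikes, labels=np.full(3, "a"), T=100.0, dt=0.1)
        np.testing.assert_array_equal(sorted_raster(spk), [0, 1, 2])
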