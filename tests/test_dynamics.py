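"""Rate dynamics: transfer function, OU noise, protocols, integration."""

import numpy as np
import pytest
from scipy.special import erf

from seqspeed import (
    InputProtocol,
    NoiseSpec,
    Phase,
    TransferFunction,
    constant_protocol,
    generate_patterns,
    initial_state,
    integrate,
    make_prep_exec_protocol,
    ou_noise,
)


class TestTransferFunction:
    def test_half_activation_and_limits(self):
        tf = TransferFunction(theta=0.3, sigma=0.1, r_max=2.0)
        assert tf(0.3) == pytest.approx(1.0)
        assert tf(1e3) == pytest.approx(2.0)
        assert tf(-1e3) == pytest.approx(0.0, abs=1e-12)

    def test_known_value(self):
        # phi(0.1; theta=0, sigma=0.1) = Phi(1) = 0.8413 for unit r_max
        tf = TransferFunction(theta=0.0, sigma=0.1, r_max=1.0)
        assert tf(0.1) == pytest.approx(0.84134, abs=1e-5)

    def test_monotone(self):
        # strictly increasing over the dynamic range (float-saturated tails
        # away from theta are constant by construction)
        tf = TransferFunction()
        h = np.linspace(-0.4, 0.4, 300)
        assert np.all(np.diff(tf(h)) > 0)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            TransferFunction(sigma=0.0)


class TestOUNoise:
    def test_zero_sd_constant(self):
        tr = ou_noise(mean=0.7, sd=0.0, tau_corr=4.0, dt=0.5, T=10.0, seed=0)
        assert np.all(tr == 0.7)

    def test_stationary_moments(self):
        """Stationary sd matches the requested 0.3 within 5%."""
        tr = ou_noise(mean=-0.2, sd=0.3, tau_corr=4.0, dt=0.5, T=2000.0, seed=1, n=64)
        assert abs(tr.mean() + 0.2) < 0.02
        assert abs(tr.std() - 0.3) < 0.015

    def test_autocorrelation_time(self):
        """Lag-tau_corr autocorrelation is e^-1 of lag-0 within sampling error."""
        dt, tau_c = 0.5, 4.0
        tr = ou_noise(mean=0.0, sd=1.0, tau_corr=tau_c, dt=dt, T=4000.0, seed=2, n=32)
        lag = int(tau_c / dt)
        x = tr - tr.mean(axis=1, keepdims=True)
        c0 = (x * x).mean()
        cl = (x[:, :-lag] * x[:, lag:]).mean()
        assert cl / c0 == pytest.approx(np.exp(-1), abs=0.05)

    def test_reproducible(self):
        a = ou_noise(0.0, 0.3, 4.0, 0.5, 50.0, seed=7, n=3)
        b = ou_noise(0.0, 0.3, 4.0, 0.5, 50.0, seed=7, n=3)
        np.testing.assert_array_equal(a, b)


class TestProtocols:
    def test_phases_must_abut(self):
        with pytest.raises(ValueError):
            InputProtocol(phases=(Phase(0.0, 10.0, 0, 0), Phase(20.0, None, 0, 0)))

    def test_prep_exec_structure(self):
        prot = make_prep_exec_protocol(
            prep_duration=200.0,
            cue_duration=10.0,
            cue_amplitude=1.0,
            prep_inputs=(-2.0, 0.0),
            exec_inputs=(-0.3, -0.3),
        )
        assert len(prot.phases) == 3
        assert prot.phase_at(5.0).cue_amplitude == 1.0
        assert prot.phase_at(100.0).cue_amplitude == 0.0
        assert prot.phase_at(100.0).I_a == -2.0
        assert prot.phase_at(300.0).I_a == -0.3

    def test_cue_longer_than_prep_rejected(self):
        with pytest.raises(ValueError):
            make_prep_exec_protocol(10.0, 20.0, 1.0, (0, 0), (0, 0))

    def test_continuum_mixing(self):
        """Per-neuron current is z_i I_s + (1 - z_i) I_a."""
        from seqspeed.dynamics import _neuron_currents

        z = np.array([0.0, 0.25, 1.0])
        ph = Phase(0.0, None, I_a=-1.0, I_s=0.6)
        np.testing.assert_allclose(
            _neuron_currents(ph, z, None), [-1.0, -0.6, 0.6]
        )


class TestIntegration:
    def test_relaxation_to_fixed_point(self):
        """J=0, constant input: r -> phi(I) with e-fold time tau."""
        tf = TransferFunction(theta=0.0, sigma=0.1)
        z = np.zeros(4)
        prot = constant_protocol(0.05, 0.0)
        r0 = np.zeros(4)
        traj = integrate(None, r0, prot, tf, tau=10.0, dt=0.5, T=200.0, z=z)
        target = tf(0.05)
        np.testing.assert_allclose(traj.rates[-1], target, atol=1e-6)
        # e-fold: at t = tau the gap has shrunk to ~exp(-1)
        k = int(10.0 / 0.5)
        gap = (target - traj.rates[k]) / (target - traj.rates[0])
        assert gap == pytest.approx(np.exp(-1), abs=0.03)

    def test_rates_bounded(self):
        tf = TransferFunction(r_max=1.0)
        pats = generate_patterns(4, 50, seed=0)
        rng = np.random.default_rng(1)
        J = rng.normal(0, 0.3, (50, 50))
        r0 = initial_state(pats, tf)
        traj = integrate(
            J, r0, constant_protocol(0.3, -0.2), tf, z=np.full(50, 0.5), T=100.0
        )
        assert traj.rates.min() >= 0.0
        assert traj.rates.max() <= 1.0 + 1e-12

    def test_dt_too_coarse_rejected(self):
        tf = TransferFunction()
        with pytest.raises(ValueError):
            integrate(
                None, np.zeros(2), constant_protocol(0, 0), tf, tau=10.0, dt=2.0, z=np.zeros(2)
            )

    def test_noisy_runs_seeded(self):
        tf = TransferFunction()
        prot = constant_protocol(0.0, 0.0, noise=NoiseSpec(sd=0.3, tau_corr=4.0))
        kw = dict(tau=10.0, dt=0.5, T=50.0, z=np.zeros(8))
        a = integrate(None, np.zeros(8), prot, tf, seed=3, **kw)
        b = integrate(None, np.zeros(8), prot, tf, seed=3, **kw)
        c = integrate(None, np.zeros(8), prot, tf, seed=4, **kw)
        np.testing.assert_array_equal(a.rates, b.rates)
        assert not np.array_equal(a.rates, c.rates)

    def test_initial_state_modes(self):
        tf = TransferFunction(theta=0.0, sigma=0.1)
        pats = generate_patterns(3, 100, seed=5)
        r = initial_state(pats, tf, mode="rate-clamp")
        # strongly positive first-pattern entries start near r_max
        assert np.all(r[pats.xi[0] > 0.5] > 0.99)
        assert np.all(initial_state(pats, tf, mode="zero") == 0.0)


class TestStepRefinement:
    def test_first_order_dt_convergence(self, standard_two_pop):
        """Forward Euler converges at first order: the pointwise error
        against a dt/4 reference halves when dt is halved.  (Pointwise
        rates near the steep transfer transition carry O(dt) errors of a
        few percent at any practical step, so the convergence *rate* is
        the meaningful check; the measured speed is dt-stable below.)"""
        patterns, conn, params = standard_two_pop
        tf = params.tf
        r0 = initial_state(patterns, tf)
        finals = {}
        for dt in (0.5, 0.25, 0.125):
            traj = integrate(
                conn,
                r0,
                constant_protocol(0.0, 0.0),
                tf,
                tau=params.tau,
                dt=dt,
                T=30.0,
                record_rates=True,
            )
            finals[dt] = traj.rates[-1]
        err_coarse = np.abs(finals[0.5] - finals[0.125]).max()
        err_fine = np.abs(finals[0.25] - finals[0.125]).max()
        assert 1.5 <= err_coarse / err_fine <= 4.0

    def test_halving_dt_leaves_speed_unchanged(self, standard_two_pop):
        """The measured retrieval speed is dt-converged to < 2%."""
        from seqspeed import measure_speed, StandardParams

        patterns, conn, params = standard_two_pop
        speeds = []
        for dt in (1.0, 0.5):
            p = StandardParams(**{**params.__dict__, "dt": dt})
            speeds.append(
                measure_speed(patterns, conn, p, 0.0, -0.5, T=900.0).speed
            )
        assert abs(speeds[0] - speeds[1]) / speeds[1] < 0.02
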