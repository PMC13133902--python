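"""Sequential three-state model, IRF convolution, and transient fitting."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from darktrap import kinetics as K
from darktrap import synthetic as S


class TestPopulations:
    def test_initial_condition(self):
        p2, p1, p0 = K.populations(0.0, 100e-15, 94e-12)
        assert (p2, p1, p0) == (1.0, 0.0, 0.0)

    def test_long_time_limit(self):
        p2, p1, p0 = K.populations(1e-8, 100e-15, 94e-12)
        assert p2 == pytest.approx(0.0, abs=1e-12)
        assert p1 == pytest.approx(0.0, abs=1e-12)
        assert p0 == pytest.approx(1.0, abs=1e-12)

    def test_against_numeric_rate_equation_solution(self):
        # independent oracle: integrate dP/dt with an ODE solver
        tau1, tau2 = 100e-15, 94e-12
        k1, k2 = 1 / tau1, 1 / tau2

        def rhs(t, y):
            return [-k1 * y[0], k1 * y[0] - k2 * y[1], k2 * y[1]]

        t_eval = np.array([1e-12])
        sol = solve_ivp(
            rhs, (0, 1e-12), [1.0, 0.0, 0.0], t_eval=t_eval,
            rtol=1e-11, atol=1e-14, method="DOP853",
        )
        p2, p1, p0 = K.populations(1e-12, tau1, tau2)
        assert p2 == pytest.approx(sol.y[0, -1], abs=1e-8)
        assert p1 == pytest.approx(sol.y[1, -1], abs=1e-8)
        assert p0 == pytest.approx(sol.y[2, -1], abs=1e-8)

    def test_conservation_exact(self, rng):
        t = rng.uniform(0, 1e-9, 100)
        p2, p1, p0 = K.populations(t, 100e-15, 94e-12)
        assert np.all(p2 + p1 + p0 == 1.0)
        for p in (p2, p1, p0):
            assert np.all((p >= 0) & (p <= 1))

    def test_continuity_at_degenerate_rates(self):
        tau = 1e-12
        t = np.linspace(0, 5e-12, 50)
        just_above = K.populations(t, tau, tau * (1 + 1e-8))
        at_limit = K.populations(t, tau, tau * (1 + 1e-10))
        for a, b in zip(just_above, at_limit):
            assert np.max(np.abs(a - b)) < 1e-7

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            K.populations(-1e-12, 1e-12, 1e-11)


class TestConvolveIrf:
    def test_zero_sigma_is_step_exponential(self):
        t = np.linspace(-1e-12, 5e-12, 100)
        out = K.convolve_irf(1e-12, 2.0, t, t0=0.0, irf_sigma=0.0)
        expected = np.where(t >= 0, 2.0 * np.exp(-np.clip(t, 0, None) / 1e-12), 0.0)
        assert np.allclose(out, expected)

    def test_small_sigma_approaches_step_exponential(self):
        tau, sigma = 1e-12, 1e-17
        t = np.linspace(10 * sigma, 5e-12, 50)
        out = K.convolve_irf(tau, 1.0, t, 0.0, sigma)
        assert np.allclose(out, np.exp(-t / tau), rtol=1e-9)

    def test_half_amplitude_at_time_zero(self):
        # at t = t0 with sigma << tau the EMG passes through A/2
        val = K.convolve_irf(1e-11, 3.0, 0.0, 0.0, 1e-14)
        assert val == pytest.approx(1.5, rel=1e-3)

    @pytest.mark.parametrize("sigma", [0.0, 40e-15, 200e-15])
    def test_area_conserved_under_convolution(self, sigma):
        # quadrature oracle: integral of the EMG equals A * tau for any sigma
        tau, amp = 0.8e-12, 1.7
        area, _ = quad(
            lambda t: K.convolve_irf(tau, amp, t, 0.0, sigma),
            -4e-12, 2e-11, limit=400, points=[0.0, 5 * sigma],
        )
        assert area == pytest.approx(amp * tau, rel=1e-6)

    def test_no_overflow_at_late_times(self):
        # fast component at very late delay: naive formula overflows
        out = K.convolve_irf(100e-15, 1.0, 400e-12, 0.0, 80e-15)
        assert np.isfinite(out) and out >= 0

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            K.convolve_irf(0.0, 1.0, 0.0)


class TestSignals:
    @pytest.fixture
    def params(self, reference_kinetics):
        return reference_kinetics

    def test_prompt_reduces_to_single_decay_without_s1_weight(self, params):
        from dataclasses import replace

        p = replace(params, amp_s1=0.0, baseline=0.0)
        t = np.geomspace(1e-15, 2e-12, 50)
        assert np.allclose(
            K.prompt_signal(p, t),
            K.convolve_irf(p.tau_fast, p.amp_s2, t, p.t0, p.irf_sigma),
        )

    def test_prompt_late_tail_is_slow_exponential(self, params):
        # for t >> tau_fast only the trapped-state term survives
        t = np.geomspace(5e-12, 200e-12, 30)
        signal = K.prompt_signal(params, t)
        expected = params.baseline + params.amp_s1 * np.exp(-t / params.tau_slow)
        assert np.allclose(signal, expected, rtol=1e-3)

    def test_pre_pulse_is_baseline(self, params):
        t = np.array([-2e-12, -1e-12])
        assert np.allclose(K.prompt_signal(params, t), params.baseline, atol=1e-12)
        assert np.allclose(K.delayed_signal(params, t), params.baseline, atol=1e-12)

    def test_delayed_full_recovery(self, params):
        val = K.delayed_signal(params, np.array([2e-9]))
        assert val[0] == pytest.approx(params.baseline + params.amp_s0, rel=1e-6)

    def test_delayed_monotone_rise(self, params):
        t = np.linspace(0.5e-12, 400e-12, 200)
        assert np.all(np.diff(K.delayed_signal(params, t)) >= 0)

    def test_delayed_rise_constant_matches_slow_lifetime(self, params):
        # self-consistency: fit exp recovery to the generated delayed curve
        from scipy.optimize import curve_fit

        t = np.linspace(1e-12, 400e-12, 100)
        y = K.delayed_signal(params, t)

        def model(t, tau):
            return params.baseline + params.amp_s0 * (1 - np.exp(-t / tau))

        popt, _ = curve_fit(model, t, y, p0=[50e-12])
        assert popt[0] == pytest.approx(params.tau_slow, rel=1e-2)


class TestFitTransients:
    def _make_pair(self, params, scale, seed):
        prompt = S.generate_transient(
            params, noise=S.NoiseModel(scale=scale, seed=seed), channel="prompt"
        )
        delayed = S.generate_transient(
            params, noise=S.NoiseModel(scale=scale, seed=seed + 10_000), channel="delayed"
        )
        return prompt, delayed

    def test_noiseless_round_trip(self, reference_kinetics):
        prompt, delayed = self._make_pair(reference_kinetics, 0.0, 0)
        init = K.KineticParams(
            tau_fast=60e-15, tau_slow=60e-12, amp_s2=0.7, amp_s1=0.3,
            amp_s0=0.8, baseline=0.0, irf_sigma=70e-15,
        )
        res = K.fit_transients(prompt, delayed, init)
        assert res.converged
        truth = reference_kinetics
        assert res.params.tau_fast == pytest.approx(truth.tau_fast, rel=1e-6)
        assert res.params.tau_slow == pytest.approx(truth.tau_slow, rel=1e-6)
        assert res.params.amp_s2 == pytest.approx(truth.amp_s2, rel=1e-6)
        assert res.params.irf_sigma == pytest.approx(truth.irf_sigma, rel=1e-5)

    def test_swapped_initial_guess_converges_to_ordered_optimum(self, reference_kinetics):
        prompt, delayed = self._make_pair(reference_kinetics, 0.02, 42)
        swapped = K.KineticParams(
            tau_fast=50e-12, tau_slow=80e-15, amp_s2=0.5, amp_s1=0.5,
            amp_s0=1.0, irf_sigma=80e-15,
        )
        res = K.fit_transients(prompt, delayed, swapped, fixed={"irf_sigma"})
        assert res.converged
        assert res.params.tau_fast < res.params.tau_slow
        assert res.params.tau_fast == pytest.approx(100e-15, rel=0.2)
        assert res.params.tau_slow == pytest.approx(94e-12, rel=0.1)

    def test_recovery_within_three_sigma_across_replicates(self, reference_kinetics):
        hits = 0
        n_rep = 100
        init = K.KineticParams(
            tau_fast=150e-15, tau_slow=60e-12, amp_s2=0.8, amp_s1=0.4,
            amp_s0=0.9, baseline=0.0, irf_sigma=80e-15,
        )
        for seed in range(n_rep):
            prompt, delayed = self._make_pair(reference_kinetics, 0.05, seed)
            res = K.fit_transients(prompt, delayed, init, fixed={"irf_sigma"})
            if not res.converged:
                continue
            ok_fast = abs(res.params.tau_fast - 100e-15) <= 3 * res.uncertainties.get(
                "tau_fast", np.inf
            )
            ok_slow = abs(res.params.tau_slow - 94e-12) <= 3 * res.uncertainties.get(
                "tau_slow", np.inf
            )
            if ok_fast and ok_slow:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_invariant_under_signal_rescale_and_t0_shift(self, reference_kinetics):
        from dataclasses import replace

        prompt, delayed = self._make_pair(reference_kinetics, 0.03, 7)
        init = K.KineticParams(
            tau_fast=150e-15, tau_slow=60e-12, amp_s2=0.8, amp_s1=0.4,
            amp_s0=0.9, irf_sigma=80e-15,
        )
        base = K.fit_transients(prompt, delayed, init, fixed={"irf_sigma"})

        scale, shift = 250.0, 3e-12
        prompt2 = K.Transient(
            prompt.delays + shift, prompt.signal * scale,
            prompt.sigma * scale, "prompt",
        )
        delayed2 = K.Transient(
            delayed.delays + shift, delayed.signal * scale,
            delayed.sigma * scale, "delayed",
        )
        init2 = replace(init, amp_s2=init.amp_s2 * scale, amp_s1=init.amp_s1 * scale,
                        amp_s0=init.amp_s0 * scale, t0=shift)
        res2 = K.fit_transients(prompt2, delayed2, init2, fixed={"irf_sigma"})
        assert res2.params.tau_fast == pytest.approx(base.params.tau_fast, rel=1e-6)
        assert res2.params.tau_slow == pytest.approx(base.params.tau_slow, rel=1e-6)
        assert res2.params.t0 - shift == pytest.approx(base.params.t0, abs=1e-16)

    def test_degenerate_data_flagged(self):
        delays = np.linspace(-0.5e-12, 400e-12, 20)
        flat = K.Transient(delays, np.ones(20), np.ones(20) * 0.01, "prompt")
        init = K.KineticParams(tau_fast=1e-13, tau_slow=1e-10)
        res = K.fit_transients(flat, None, init)
        assert not res.converged
        assert "degenerate" in res.message

    def test_too_few_points_rejected(self):
        delays = np.linspace(0, 1e-12, 5)
        tr = K.Transient(delays, np.exp(-delays / 1e-13), None, "prompt")
        with pytest.raises(ValueError, match="8 points"):
            K.fit_transients(tr, None, K.KineticParams(1e-13, 1e-10))
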