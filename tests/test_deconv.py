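import math

import numpy as np
import pytest

import synaptoglu as sg


TRAIN_QUANTA = np.array([12.0, 6.0, 4.0, 3.0])
TRAIN_PROTOCOL = sg.StimulusProtocol(np.arange(4) * 0.1)


def noiseless_train(quanta=TRAIN_QUANTA, protocol=TRAIN_PROTOCOL, tau=None):
    kernel = sg.KernelModel() if tau is None else sg.KernelModel(tau=tau)
    cfg = sg.SynthConfig(noise_frames=0.0, kernel=kernel)
    return sg.render_fluorescence(quanta, protocol, cfg).truth_dff, cfg


class TestEstimateSnr:
    def test_arithmetic_definition(self):
        rng = np.random.default_rng(0)
        dt = 0.01
        base = rng.normal(0, 0.03, 300)
        resp = np.concatenate([base, 0.30 + np.zeros(50)])
        ts = sg.TimeSeries(0, dt, resp, units=sg.Units.DFF)
        snr = sg.estimate_snr(ts, (0.0, 299 * dt))
        assert snr == pytest.approx(100.0, rel=0.2)

    def test_noiseless_baseline_gives_sentinel(self):
        v = np.concatenate([np.zeros(100), np.ones(20)])
        ts = sg.TimeSeries(0, 0.01, v, units=sg.Units.DFF)
        assert math.isinf(sg.estimate_snr(ts, (0.0, 0.99)))

    def test_known_sigma_recovered_over_seeds(self):
        # median over 50 seeds within 10% of the configured SNR
        peak, sigma = 0.30, 0.003
        snrs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = rng.normal(0, sigma, 200)
            resp = peak * np.exp(-np.arange(100) * 0.01 / 0.03843)
            ts = sg.TimeSeries(0, 0.01, np.concatenate([base, resp + rng.normal(0, sigma, 100)]),
                               units=sg.Units.DFF)
            snrs.append(sg.estimate_snr(ts, (0.0, 1.99)))
        assert np.median(snrs) == pytest.approx((peak / sigma) ** 2, rel=0.10)


class TestWienerDeconvolve:
    def test_kernel_input_yields_unit_impulse(self):
        n, dt, tau = 256, 0.01, 0.03843
        h = np.exp(-np.arange(n) * dt / tau)
        h /= h.sum() * dt
        ts = sg.TimeSeries(0, dt, h, units=sg.Units.DFF)
        dec = sg.wiener_deconvolve(ts, sg.KernelModel(tau=tau), sg.INF_SNR)
        peak = int(np.argmax(dec.values))
        assert peak == 0
        off = np.delete(dec.values, peak)
        assert np.max(np.abs(off)) < 1e-6 * dec.values[peak]

    def test_delayed_kernel_shifts_impulse(self):
        n, dt, tau = 256, 0.01, 0.03843
        delay = 50
        h = np.zeros(n)
        h[delay:] = np.exp(-np.arange(n - delay) * dt / tau)
        h /= np.exp(-np.arange(n) * dt / tau).sum() * dt
        ts = sg.TimeSeries(0, dt, h, units=sg.Units.DFF)
        dec = sg.wiener_deconvolve(ts, sg.KernelModel(tau=tau), sg.INF_SNR)
        assert int(np.argmax(dec.values)) == delay

    def test_nonpositive_snr_rejected(self):
        ts = sg.TimeSeries(0, 0.01, np.ones(64), units=sg.Units.DFF)
        with pytest.raises(ValueError):
            sg.wiener_deconvolve(ts, sg.KernelModel(), 0.0)

    def test_noisy_train_per_pulse_release(self):
        # 1% frame noise; the per-pulse release of the 10-trial average
        # response (the standard per-cell averaging) tracks true quanta
        peak = noiseless_train()[0].values.max()
        avg = None
        cfg = sg.SynthConfig(seed=0, noise_frames=0.01 * peak * 1000.0,
                             baseline_f0=1000.0)
        for seed in range(10):
            cfg_i = sg.SynthConfig(seed=seed, noise_frames=cfg.noise_frames)
            r = sg.render_fluorescence(TRAIN_QUANTA, TRAIN_PROTOCOL, cfg_i,
                                       cfg_i.rng(), pre_time=1.0)
            avg = r.dff.values if avg is None else avg + r.dff.values
            grid = r.dff
        ts = sg.TimeSeries(grid.t0, grid.dt, avg / 10.0, units=sg.Units.DFF)
        snr = sg.estimate_snr(ts, (ts.t0, -0.02))
        dec = sg.wiener_deconvolve(ts, cfg.kernel, snr)
        per, _ = sg.cumulative_release(dec, TRAIN_PROTOCOL, mode="peak")
        true = TRAIN_QUANTA / TRAIN_QUANTA[0]
        assert np.max(np.abs(per / per[0] - true) / true) < 0.05


class TestLinearDeconvolve:
    def test_matched_exponential_collapses_to_onset_impulse(self):
        # finely sampled (dt << tau) so the first-order operator's residual
        # is negligible: a single positive onset deflection, ~0 afterwards
        tau = 0.03843
        dt = tau / 1000.0
        amp = 0.3
        t = np.arange(0, 10 * tau, dt)
        s = np.where(t >= 100 * dt, amp * np.exp(-(t - 100 * dt) / tau), 0.0)
        ts = sg.TimeSeries(0, dt, s, units=sg.Units.DFF)
        dec = sg.linear_deconvolve(ts, tau)
        onset = int(np.argmax(dec.values))
        assert dec.values[onset] > 0
        assert dec.values[onset] == pytest.approx(amp / dt, rel=1e-3)
        after = dec.values[onset + 1 : -1]
        assert np.max(np.abs(after)) < 1e-3 * amp / dt

    def test_constant_signal_gives_rate_c_over_tau(self):
        ts = sg.TimeSeries(0, 0.01, np.full(100, 0.4), units=sg.Units.DFF)
        dec = sg.linear_deconvolve(ts, 0.05)
        np.testing.assert_allclose(dec.values, 0.4 / 0.05, rtol=1e-12)

    def test_per_pulse_ratio_oracle(self):
        dff, cfg = noiseless_train()
        dec = sg.linear_deconvolve(dff, cfg.kernel.tau)
        per, _ = sg.cumulative_release(dec, TRAIN_PROTOCOL, mode="integral")
        true = TRAIN_QUANTA / TRAIN_QUANTA[0]
        assert np.max(np.abs(per / per[0] - true) / true) < 0.02

    def test_sigma_decreases_with_coarser_sampling(self):
        # the 2 sigma_s^2/dt^2 term dominates: halving dt doubles sigma_r
        s = np.full(100, 0.1)
        fine = sg.linear_deconvolve(sg.TimeSeries(0, 0.005, s, units=sg.Units.DFF),
                                    0.05, sigma_s=0.01)
        coarse = sg.linear_deconvolve(sg.TimeSeries(0, 0.01, s, units=sg.Units.DFF),
                                      0.05, sigma_s=0.01)
        assert fine.sigma[0] > coarse.sigma[0]

    def test_printed_error_formula_available(self):
        ts = sg.TimeSeries(0, 0.01, np.full(50, 0.2), units=sg.Units.DFF)
        dec = sg.linear_deconvolve(ts, 0.05, sigma_s=0.01, sigma_tau=0.001,
                                   formula="printed")
        expected = 2 * 0.01 / 0.01 - 0.01 / 0.05 - (0.2 / 0.05**2) * 0.001
        assert dec.sigma[0] == pytest.approx(expected, rel=1e-9)
        assert dec.flags["sigma_formula"] == "printed"

    def test_last_sample_copied_and_flagged(self):
        ts = sg.TimeSeries(0, 0.01, np.linspace(1, 0, 50), units=sg.Units.DFF)
        dec = sg.linear_deconvolve(ts, 0.05)
        assert dec.values[-1] == dec.values[-2]
        assert dec.flags["last_sample_copied"]


class TestEstimateTau:
    def test_exact_on_noiseless_impulse_response(self):
        dff, cfg = noiseless_train(quanta=np.array([12.0]),
                                   protocol=sg.StimulusProtocol([0.0]))
        fit = sg.estimate_tau(dff, (0.02, dff.t_end))
        assert fit.tau == pytest.approx(cfg.kernel.tau, rel=1e-6)
        assert fit.upper_bound

    def test_default_condition_recovered_under_noise(self):
        cfg = sg.SynthConfig(seed=8, noise_frames=3.0)
        r = sg.render_fluorescence(np.array([12.0]), sg.StimulusProtocol([0.0]),
                                   cfg, cfg.rng())
        fit = sg.estimate_tau(r.dff, (0.01, r.dff.t_end))
        assert fit.tau == pytest.approx(0.03843, rel=0.05)

    def test_residual_release_inflates_estimate(self):
        # late release during the decay makes the fit an upper bound
        proto = sg.StimulusProtocol([0.0, 0.02, 0.04])
        dff, cfg = noiseless_train(quanta=np.array([12.0, 3.0, 1.0]), protocol=proto)
        fit = sg.estimate_tau(dff, (0.05, dff.t_end))
        assert fit.tau >= cfg.kernel.tau * 0.999


class TestMethodProperties:
    def test_both_methods_agree_on_relative_release(self):
        dff, cfg = noiseless_train()
        lin = sg.linear_deconvolve(dff, cfg.kernel.tau)
        wie = sg.wiener_deconvolve(dff, cfg.kernel, sg.INF_SNR)
        pl, _ = sg.cumulative_release(lin, TRAIN_PROTOCOL, mode="integral")
        pw, _ = sg.cumulative_release(wie, TRAIN_PROTOCOL, mode="integral")
        np.testing.assert_allclose(pl / pl[0], pw / pw[0], rtol=0.10)

    @pytest.mark.parametrize("method", ["linear", "wiener"])
    def test_linearity(self, method):
        d1, cfg = noiseless_train(quanta=np.array([12.0, 0, 0, 0]))
        d2, _ = noiseless_train(quanta=np.array([0, 6.0, 4.0, 3.0]))
        combo = sg.TimeSeries(d1.t0, d1.dt, 2.0 * d1.values + 0.5 * d2.values,
                              units=sg.Units.DFF)
        if method == "linear":
            f = lambda ts: sg.linear_deconvolve(ts, cfg.kernel.tau).values
        else:
            f = lambda ts: sg.wiener_deconvolve(ts, cfg.kernel, sg.INF_SNR).values
        np.testing.assert_allclose(f(combo), 2.0 * f(d1) + 0.5 * f(d2), atol=1e-9)

    def test_cumulative_release_homogeneity(self):
        dff, cfg = noiseless_train()
        dec = sg.linear_deconvolve(dff, cfg.kernel.tau)
        scaled = sg.DeconvolvedTrace(t0=dec.t0, dt=dec.dt, values=3.0 * dec.values,
                                     sigma=None, tau_used=dec.tau_used,
                                     method=dec.method)
        a, ca = sg.cumulative_release(dec, TRAIN_PROTOCOL)
        b, cb = sg.cumulative_release(scaled, TRAIN_PROTOCOL)
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-9)
        np.testing.assert_allclose(cb, 3.0 * ca, rtol=1e-9)

    def test_optical_pool_estimate_matches_oracle(self):
        # deterministic depletion pool read out through the reporter model
        proto = sg.StimulusProtocol.regular(25, 100.0)
        pool = sg.PoolModel(n_rrp=100, p_r=0.3, refill_rate=0.0)
        released = sg.simulate_pool_train(proto, pool, deterministic=True).released
        cfg = sg.SynthConfig(noise_frames=0.0)
        dff = sg.render_fluorescence(released, proto, cfg).truth_dff
        dec = sg.linear_deconvolve(dff, cfg.kernel.tau)
        per, _ = sg.cumulative_release(dec, proto)
        est = sg.y1_over_intercept(per)
        assert est.p_apparent == pytest.approx(0.30, abs=0.02)
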