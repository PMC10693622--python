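"""Pause segmentation, E1 drop statistics, and relaxation regression."""

import numpy as np
import pytest
from scipy import stats

from conftest import bench_ventilator, make_actuator
from viscovent.estimation import (
    NoPauseError,
    estimate_E1,
    estimate_from_trace,
    fit_relaxation,
    segment_cycles,
    segment_pause,
)
from viscovent.ventilator import (
    LungSettings,
    NoiseModel,
    PressureTrace,
    VentilatorSettings,
    simulate_cycle,
    simulate_run,
)


def handmade_trace():
    """Three-phase piecewise trace with landmarks planted by construction."""
    fs = 31.25
    dt = 1 / fs
    n_insp, n_pause, n_exp = 30, 40, 50
    flow = np.concatenate(
        [np.zeros(1), np.full(n_insp, 0.15), np.zeros(n_pause), np.full(n_exp, -0.1)]
    )
    n = flow.size
    t = np.arange(n) * dt
    pressure = np.concatenate(
        [
            np.linspace(0, 10.2, n_insp + 1),  # ramp to planted Ppeak
            np.full(n_pause, 0.0),  # filled below
            np.linspace(7.0, 1.0, n_exp),
        ]
    )
    # Pause: drop from planted P1 = 9.0 to plateau P2 = 7.0
    pause_t = np.arange(n_pause) * dt
    pressure[n_insp + 1 : n_insp + 1 + n_pause] = 7.0 + 2.0 * np.exp(-pause_t / 0.2)
    volume = np.zeros(n)
    return PressureTrace(
        sampling_rate=fs, time=t, pressure=pressure, flow=flow, volume=volume
    ), (n_insp, n_pause)


class TestSegmentation:
    def test_handmade_landmarks_recovered_exactly(self):
        trace, (n_insp, n_pause) = handmade_trace()
        seg = segment_pause(trace)
        dt = 1 / trace.sampling_rate
        assert seg.t1 == pytest.approx(n_insp * dt)
        assert seg.t2 == pytest.approx((n_insp + 1) * dt)
        assert seg.Ppeak == pytest.approx(10.2)
        assert seg.P1 == pytest.approx(9.0)
        assert seg.pause_window == (n_insp + 1, n_insp + 1 + n_pause)
        # P2: mean of the final 20% of the pause (tail has settled near 7.0)
        assert seg.P2 == pytest.approx(7.0, abs=0.01)

    def test_roundtrip_drop_matches_calibrated_e1(self, default_lung):
        trace = simulate_cycle(bench_ventilator(), default_lung, make_actuator(25.0))
        assert segment_pause(trace).drop == pytest.approx(3.48, rel=0.02)

    def test_no_actuator_drop_is_zero(self, default_lung):
        trace = simulate_cycle(bench_ventilator(), default_lung)
        assert segment_pause(trace).drop == pytest.approx(0.0, abs=1e-9)

    def test_trace_without_pause_raises(self, default_lung):
        trace = simulate_cycle(bench_ventilator(pause=0.0), default_lung)
        with pytest.raises(NoPauseError):
            segment_pause(trace)

    def test_landmark_ordering_invariant(self, default_lung):
        trace = simulate_cycle(bench_ventilator(), default_lung, make_actuator())
        seg = segment_pause(trace)
        assert seg.t1 <= seg.t2
        assert seg.Ppeak >= seg.P1 >= seg.P2

    def test_truncation_bias_follows_exponential_law(self, default_lung):
        # The measured drop underestimates E1 by the mean residual decay
        # over the plateau window — computable in closed form.
        act = make_actuator(25.0, pwm=68.63)
        trace = simulate_cycle(
            bench_ventilator(pause=0.35), default_lung, act
        )
        seg = segment_pause(trace)
        lo, hi = seg.pause_window
        dt = 1 / trace.sampling_rate
        n_pl = max(int(round(0.2 * (hi - lo))), 5)
        k = np.arange(hi - lo - n_pl, hi - lo)
        predicted = act.e1_equiv * (1 - np.mean(np.exp(-k * dt / act.tau)))
        assert seg.drop == pytest.approx(predicted, abs=1e-9)

    def test_truncation_bias_small_for_fast_return_stroke(self, default_lung):
        # At the fast calibrated PWM the bias stays below 2% even for the
        # short 20%-of-cycle pause.
        for ab, e1 in ((25.0, 3.48), (30.0, 2.20)):
            trace = simulate_cycle(
                bench_ventilator(pause=0.20), default_lung, make_actuator(ab)
            )
            assert abs(segment_pause(trace).drop / e1 - 1) < 0.02


class TestE1Estimate:
    def test_gaussian_drops_recover_mean(self):
        rng = np.random.default_rng(5)
        drops = rng.normal(3.48, 0.22, size=24)
        est = estimate_E1(drops)
        assert est.mean == pytest.approx(3.48, abs=2 * 0.22 / np.sqrt(24))
        assert 0 <= est.normality_p <= 1
        assert 0 <= est.ttest_p <= 1

    def test_symmetric_sample_against_own_mean_gives_p_one(self):
        drops = np.array([2.0, 3.0, 4.0] * 4) * 1.5
        est = estimate_E1(drops, null_value=3.0 * 1.5)
        assert est.ttest_p == pytest.approx(1.0, abs=1e-12)

    def test_too_few_drops_refused(self):
        with pytest.raises(ValueError, match="n >= 8"):
            estimate_E1([3.4, 3.5, 3.6])

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            est = estimate_E1(np.full(10, 3.48))
        assert np.isnan(est.ttest_p)

    def test_normality_pvalues_uniform_under_null(self):
        # Calibration of the omnibus normality test: under Gaussian data
        # its p-values must be ~U(0,1).
        rng = np.random.default_rng(12345)
        draws = rng.standard_normal((500, 1000))
        _, pvals = stats.normaltest(draws, axis=1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestRelaxationFit:
    @pytest.mark.parametrize(
        "e0,e1,eta",
        [(7.0999, 3.48, 1.181), (6.7999, 3.48, 0.403),
         (6.5999, 2.20, 1.166), (6.6999, 2.20, 0.442)],
    )
    def test_noiseless_roundtrip_recovers_parameters(self, e0, e1, eta):
        t = np.arange(0, 1.6, 1 / 31.25)
        p = e0 + e1 * np.exp(-e1 * t / eta)
        fit = fit_relaxation(t, p, E1_fixed=e1)
        assert fit.E0_hat == pytest.approx(e0, abs=1e-3)
        assert fit.eta_hat == pytest.approx(eta, abs=1e-3)
        assert fit.R2 == pytest.approx(1.0, abs=1e-9)
        assert fit.tau_hat == pytest.approx(eta / e1, rel=1e-3)

    def test_log_linear_variant_agrees_on_clean_data(self):
        t = np.arange(0, 3.0, 1 / 31.25)
        p = 7.0999 + 3.48 * np.exp(-3.48 * t / 1.181)
        fit = fit_relaxation(t, p, E1_fixed=3.48, method="log-linear")
        assert fit.eta_hat == pytest.approx(1.181, rel=0.05)

    def test_constant_segment_flagged(self):
        t = np.arange(0, 1.0, 1 / 31.25)
        with pytest.warns(UserWarning, match="constant pressure"):
            fit = fit_relaxation(t, np.full_like(t, 7.1), E1_fixed=3.48)
        assert np.isnan(fit.R2)
        assert fit.eta_hat == 0.0

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match=">= 10 samples"):
            fit_relaxation(np.arange(5) * 0.032, np.ones(5), E1_fixed=1.0)

    def test_estimator_consistency_under_noise(self, default_lung):
        # eta_hat over noisy replicates is unbiased within 2 SE.
        eta_true, e1_true = 0.403, 3.48
        act = make_actuator(25.0, pwm=74.51)
        etas = []
        for seed in range(100):
            noise = NoiseModel(pressure_sd=0.1, drop_sd=0.0, seed=seed)
            trace = simulate_cycle(
                bench_ventilator(pause=0.35), default_lung, act, noise
            )
            seg = segment_pause(trace)
            lo, hi = seg.pause_window
            t = trace.time[lo:hi] - trace.time[lo]
            etas.append(
                fit_relaxation(t, trace.pressure[lo:hi], E1_fixed=e1_true).eta_hat
            )
        etas = np.asarray(etas)
        se = etas.std(ddof=1) / np.sqrt(len(etas))
        assert abs(etas.mean() - eta_true) < 2 * se + 0.01 * eta_true


class TestPipeline:
    def test_estimate_from_trace_full_pipeline(self, default_lung):
        noise = NoiseModel(pressure_sd=0.05, drop_sd=0.1, seed=9)
        trace = simulate_run(
            bench_ventilator(pause=0.35), default_lung, make_actuator(25.0),
            noise, n_cycles=12,
        )
        res = estimate_from_trace(trace)
        assert res.E1_hat == pytest.approx(3.48, abs=0.2)
        assert res.fit.R2 > 0.9
        assert res.e1.n == 12
        assert len(segment_cycles(trace)) == 12
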