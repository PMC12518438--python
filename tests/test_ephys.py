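"""AP metrics, current extraction, and model-fit round trips."""

import numpy as np
import pytest

from cardiokit import ephys
from cardiokit.errors import AnalysisError, ProtocolError
from cardiokit.io import SweepSet, TimeSeriesRecording
from cardiokit.synth import (
    ApSimSpec,
    BoltzmannParams,
    EphysSimSpec,
    ItoParams,
    RecoveryParams,
    gen_ap_trace,
    gen_vclamp_sweeps,
)


def split_ik1(ss, cap):
    n = len(ss.sweeps) // 2
    ctrl = SweepSet(ss.sweeps[:n], ss.protocol.iloc[:n].reset_index(drop=True), cap, kind="ik1")
    blk = SweepSet(ss.sweeps[n:], ss.protocol.iloc[n:].reset_index(drop=True), cap, kind="ik1")
    return ctrl, blk


class TestMeasureAp:
    def test_noise_free_template_recovered_within_one_sample(self):
        spec = ApSimSpec(noise_sd_mv=0.0)
        rec, truth = gen_ap_trace(spec)
        m = ephys.measure_ap(rec)
        tol_ms = 1000.0 / spec.sampling_rate
        assert m.rmp_mv == pytest.approx(truth["rmp_mv"], abs=0.01)
        assert m.overshoot_mv == pytest.approx(truth["overshoot_mv"], abs=0.01)
        assert m.dvdt_max_mv_ms == pytest.approx(truth["dvdt_max_mv_ms"], rel=0.01)
        for k in ("apd20_ms", "apd50_ms", "apd90_ms", "apd_0mv_ms"):
            assert getattr(m, k) == pytest.approx(truth[k], abs=tol_ms)

    def test_apd_ordering_is_monotone(self):
        rec, _ = gen_ap_trace(ApSimSpec(seed=5))
        m = ephys.measure_ap(rec)
        assert m.apd20_ms <= m.apd50_ms <= m.apd90_ms

    def test_constant_trace_is_an_error(self):
        rec = TimeSeriesRecording(
            time=np.arange(10000) / 10000.0,
            channels={"membrane_potential": np.full(10000, -85.0)},
            sampling_rate=10000.0,
        )
        with pytest.raises(AnalysisError, match="upstroke"):
            ephys.measure_ap(rec)

    def test_too_few_beats_names_the_30th_beat_rule(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, _ = gen_ap_trace(ApSimSpec(n_beats=5, noise_sd_mv=0.0))
        with pytest.raises(AnalysisError, match="30"):
            ephys.measure_ap(rec, beat_index=30)


class TestCurrentExtraction:
    def test_ito_matches_closed_form_on_noise_free_sweep(self):
        spec = EphysSimSpec(noise_sd_pa=0.0)
        ss, truth = gen_vclamp_sweeps(spec, "iv")
        tab = ephys.extract_ito(ss)
        at60 = tab[np.isclose(tab["v_test_mv"], 60.0)].iloc[0]
        # closed form for the estimator: peak at t=0, end = analytic mean of
        # the bi-exponential over the terminal 5% window
        p, gate = spec.ito, truth["gate_at_60"]
        T = spec.step_duration_s
        t0 = T * 0.95

        def seg_mean(amp, tau):
            return amp * tau * (np.exp(-t0 / tau) - np.exp(-T / tau)) / (T - t0)

        expected = gate * (
            (p.amp_fast + p.amp_slow + p.steady)
            - (seg_mean(p.amp_fast, p.tau_fast_s) + seg_mean(p.amp_slow, p.tau_slow_s) + p.steady)
        )
        assert at60["ito_pa_pf"] == pytest.approx(expected, rel=0.01)

    def test_pure_steady_current_has_zero_ito(self):
        spec = EphysSimSpec(
            ito=ItoParams(amp_fast=0.0, amp_slow=0.0, steady=18.9), noise_sd_pa=0.0
        )
        ss, _ = gen_vclamp_sweeps(spec, "iv")
        tab = ephys.extract_ito(ss)
        assert np.allclose(tab["ito_pa_pf"], 0.0, atol=1e-9)

    def test_density_scales_inversely_with_capacitance(self):
        """Same raw currents read out at doubled capacitance halve the density."""
        spec = EphysSimSpec(noise_sd_pa=0.0, capacitance_pf=100.0)
        ss, _ = gen_vclamp_sweeps(spec, "iv")
        doubled = SweepSet(ss.sweeps, ss.protocol, capacitance_pf=200.0, kind="iv")
        t1 = ephys.extract_ito(ss)
        t2 = ephys.extract_ito(doubled)
        np.testing.assert_allclose(t1["ito_pa_pf"], 2.0 * t2["ito_pa_pf"], rtol=1e-12)

    def test_ik_constant_current_and_bruteforce_window(self, rng):
        spec = EphysSimSpec(
            ito=ItoParams(amp_fast=0.0, amp_slow=0.0, steady=20.0),
            activation=BoltzmannParams(v50_mv=-1000.0, slope_mv=5.0),  # gate ~ 1
            noise_sd_pa=5.0,
            capacitance_pf=100.0,
        )
        ss, _ = gen_vclamp_sweeps(spec, "iv")
        tab = ephys.extract_ik(ss)
        sw = ss.sweeps[0]
        row = ss.protocol.iloc[0]
        i0 = int(np.searchsorted(sw.time, row["pulse_start_s"]))
        i1 = int(np.searchsorted(sw.time, row["pulse_end_s"]))
        n_end = max(1, int(round(0.05 * (i1 - i0))))
        brute = sw.signal[i1 - n_end : i1].mean() / 100.0
        assert tab["ik_pa_pf"].iloc[0] == pytest.approx(brute, rel=1e-12)
        assert tab["ik_pa_pf"].iloc[0] == pytest.approx(20.0 / 100.0 * 100.0, rel=0.05)

    def test_ik1_difference_and_sign_convention(self):
        spec = EphysSimSpec(
            step_potentials_mv=tuple(np.arange(-120.0, -30.0, 10.0)), noise_sd_pa=0.0
        )
        ss, truth = gen_vclamp_sweeps(spec, "ik1")
        ctrl, blk = split_ik1(ss, spec.capacitance_pf)
        out = ephys.extract_ik1(ctrl, blk)
        at_m120 = out[np.isclose(out["v_test_mv"], -120.0)]["ik1_pa_pf"].iloc[0]
        assert at_m120 == pytest.approx(truth["ik1_density"][-120.0], rel=1e-9)
        assert at_m120 < 0  # inward current is negative
        # blocked == control -> zero everywhere
        zero = ephys.extract_ik1(ctrl, ctrl)
        np.testing.assert_allclose(zero["ik1_pa_pf"], 0.0, atol=1e-12)

    def test_ik1_protocol_mismatch_rejected(self):
        spec = EphysSimSpec(
            step_potentials_mv=(-120.0, -100.0, -80.0), noise_sd_pa=0.0
        )
        ss, _ = gen_vclamp_sweeps(spec, "ik1")
        ctrl, blk = split_ik1(ss, spec.capacitance_pf)
        bad = SweepSet(
            blk.sweeps[:2], blk.protocol.iloc[:2].reset_index(drop=True),
            spec.capacitance_pf, kind="ik1",
        )
        with pytest.raises(ProtocolError, match="match"):
            ephys.extract_ik1(ctrl, bad)


class TestBoltzmannFit:
    def test_exact_curve_recovered_to_1e6(self):
        v = np.arange(-80.0, 20.0, 10.0)
        y = 1.0 / (1.0 + np.exp((v + 34.0) / 5.0))
        fit = ephys.fit_boltzmann(v, y, "inactivation")
        assert fit.v50_mv == pytest.approx(-34.0, abs=1e-6)
        assert fit.slope_mv == pytest.approx(5.0, abs=1e-6)

    def test_activation_direction(self):
        v = np.arange(-40.0, 70.0, 10.0)
        y = 1.0 / (1.0 + np.exp((5.0 - v) / 12.0))
        fit = ephys.fit_boltzmann(v, y, "activation")
        assert fit.v50_mv == pytest.approx(5.0, abs=1e-6)
        assert fit.slope_mv == pytest.approx(12.0, abs=1e-6)

    def test_small_noise_leaves_v50_nearly_unbiased(self):
        """1% noise, 200 replicates: |V50 bias| < 0.5 mV."""
        v = np.arange(-80.0, 20.0, 10.0)
        y0 = 1.0 / (1.0 + np.exp((v + 34.0) / 5.0))
        rng = np.random.default_rng(0)
        est = [
            ephys.fit_boltzmann(v, y0 + rng.normal(0, 0.01, v.size), "inactivation").v50_mv
            for _ in range(200)
        ]
        assert abs(np.mean(est) + 34.0) < 0.5

    def test_flat_data_is_an_error(self):
        v = np.arange(-80.0, 20.0, 10.0)
        with pytest.raises(AnalysisError, match="transition"):
            ephys.fit_boltzmann(v, np.ones_like(v), "inactivation")


class TestBiexpFit:
    def test_round_trip_on_results_constants(self):
        """tau 48.7 / 322 ms, c1 = 55.2%: noise-free recovery < 0.1%."""
        t = np.arange(0, 0.6, 1 / 5000.0)
        y = 25.1 * np.exp(-t / 0.0487) + 20.4 * np.exp(-t / 0.322) + 18.9
        fit = ephys.fit_biexponential(t, y)
        assert fit.tau_fast_ms == pytest.approx(48.7, rel=1e-3)
        assert fit.tau_slow_ms == pytest.approx(322.0, rel=1e-3)
        assert fit.c1 == pytest.approx(25.1 / 45.5, rel=1e-3)
        assert fit.c1 + fit.c2 == pytest.approx(1.0, abs=1e-12)

    def test_single_exponential_limit(self):
        t = np.arange(0, 0.6, 1 / 5000.0)
        y = 30.0 * np.exp(-t / 0.05) + 5.0
        with np.errstate(over="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = ephys.fit_biexponential(t, y)
        amps = sorted([abs(fit.amp_fast), abs(fit.amp_slow)])
        assert amps[0] / amps[1] < 0.05  # one component vanishes

    def test_time_origin_invariance(self):
        t = np.arange(0, 0.6, 1 / 5000.0)
        y = 25.1 * np.exp(-t / 0.0487) + 20.4 * np.exp(-t / 0.322) + 18.9
        f1 = ephys.fit_biexponential(t, y)
        f2 = ephys.fit_biexponential(t + 1.234, y)
        assert f2.tau_fast_ms == pytest.approx(f1.tau_fast_ms, rel=1e-6)
        assert f2.tau_slow_ms == pytest.approx(f1.tau_slow_ms, rel=1e-6)


class TestRecoveryFit:
    def test_round_trip_on_results_constants(self):
        p = RecoveryParams(k_fast_s=0.0505, k_slow_s=1.319, frac_fast=0.6)
        t_ms = 5.0 * 1.5 ** np.arange(16)
        y = p.fraction_recovered(t_ms / 1000.0)
        fit = ephys.fit_recovery(t_ms, y)
        assert fit.k_fast_ms == pytest.approx(50.5, rel=0.01)
        assert fit.k_slow_ms == pytest.approx(1319.0, rel=0.01)
        assert fit.frac_fast == pytest.approx(0.6, abs=0.01)

    def test_model_limits_by_construction(self):
        """y(0) = 1 − a − b and y(t) → 1 as the interval grows."""
        p = RecoveryParams(k_fast_s=0.05, k_slow_s=1.3, frac_fast=0.6)
        assert p.fraction_recovered(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)
        assert p.fraction_recovered(np.array([1e3]))[0] == pytest.approx(1.0, abs=1e-12)
        t = np.geomspace(1e-3, 10.0, 50)
        y = p.fraction_recovered(t)
        assert np.all(np.diff(y) > 0)

    def test_full_protocol_recovery_curve(self):
        spec = EphysSimSpec(noise_sd_pa=0.0)
        ss, truth = gen_vclamp_sweeps(spec, "recovery")
        rc = ephys.recovery_curve(ss)
        np.testing.assert_allclose(
            rc["interval_ms"].to_numpy()[1:] / rc["interval_ms"].to_numpy()[:-1],
            1.5,
            rtol=1e-9,
        )
        fit = ephys.fit_recovery(rc["interval_ms"], rc["ratio"])
        assert fit.k_fast_ms == pytest.approx(50.5, rel=0.01)
        assert fit.k_slow_ms == pytest.approx(1319.0, rel=0.01)


class TestNoisyRecoveryStatistics:
    def test_median_relative_error_under_2pct_noise(self):
        """2% multiplicative noise, 40 seeds: median relative error < 5%."""
        t = np.arange(0, 0.6, 1 / 2000.0)
        y0 = 25.1 * np.exp(-t / 0.0487) + 20.4 * np.exp(-t / 0.322) + 18.9
        v = np.arange(-80.0, 20.0, 10.0)
        b0 = 1.0 / (1.0 + np.exp((v + 34.0) / 5.0))
        errs_tau, errs_v50 = [], []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fit = ephys.fit_biexponential(t, y0 * (1 + rng.normal(0, 0.02, t.size)))
            errs_tau.append(abs(fit.tau_fast_ms / 48.7 - 1))
            bfit = ephys.fit_boltzmann(v, b0 * (1 + rng.normal(0, 0.02, v.size)), "inactivation")
            errs_v50.append(abs(bfit.v50_mv / -34.0 - 1))
        assert np.median(errs_tau) < 0.05
        assert np.median(errs_v50) < 0.05


class TestNormalizedCurves:
    def test_availability_curve_matches_generator_truth(self):
        spec = EphysSimSpec(noise_sd_pa=0.0)
        ss, truth = gen_vclamp_sweeps(spec, "inactivation")
        curve = ephys.availability_curve(ss)
        expected = np.array(list(truth["availability"].values()))
        np.testing.assert_allclose(
            curve["g_norm"], expected / expected[0], rtol=1e-6
        )

    def test_activation_curve_normalised_at_reference(self):
        ss, _ = gen_vclamp_sweeps(EphysSimSpec(noise_sd_pa=0.0), "iv")
        curve = ephys.activation_curve(ss)
        ref = curve[np.isclose(curve["v_mv"], 60.0)]["g_norm"].iloc[0]
        assert ref == pytest.approx(1.0, abs=1e-12)
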