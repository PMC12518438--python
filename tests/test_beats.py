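"""Stimulus-locked beat analysis: oracles, metric recovery, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiokit import beats
from cardiokit.errors import AnalysisError, SpecError
from cardiokit.io import TimeSeriesRecording
from cardiokit.synth import TransientSimSpec, gen_sarcomere_trace, gen_striation_profile


def naive_filter(x, median_radius=10, mean_radius=5):
    """Window-by-window reference: shrinking-window median then mean."""
    n = len(x)
    med = np.array(
        [np.median(x[max(0, i - median_radius) : i + median_radius + 1]) for i in range(n)]
    )
    return np.array(
        [med[max(0, i - mean_radius) : i + mean_radius + 1].mean() for i in range(n)]
    )


class TestFilterSignal:
    def test_constant_signal_unchanged(self):
        x = np.full(100, 3.7)
        np.testing.assert_allclose(beats.filter_signal(x), x, atol=1e-12)

    def test_single_spike_fully_removed(self):
        x = np.zeros(200)
        x[100] = 5.0
        filt = beats.filter_signal(x)
        np.testing.assert_allclose(filt, 0.0, atol=1e-12)

    def test_matches_naive_reference_on_random_traces(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, rng.integers(30, 400))
            np.testing.assert_allclose(
                beats.filter_signal(x), naive_filter(x), atol=1e-12
            )

    def test_short_signal_rejected(self):
        with pytest.raises(SpecError, match="shorter"):
            beats.filter_signal(np.zeros(21))


class TestDetectStimuli:
    def test_events_match_generator_truth(self, short_trace):
        rec, truth = short_trace
        train = beats.detect_stimuli(rec)
        assert train.n_events == len(truth)
        np.testing.assert_allclose(
            train.stimulus_times, truth["stimulus_time_s"], atol=1.01 / rec.sampling_rate
        )

    def test_flat_channel_gives_empty_train(self):
        rec = TimeSeriesRecording(
            time=np.arange(1000) / 1000.0,
            channels={"stimulus": np.zeros(1000)},
            sampling_rate=1000.0,
        )
        assert beats.detect_stimuli(rec).n_events == 0

    def test_paper_ladder_segments_into_seven_intervals(self):
        from cardiokit.synth import gen_transient_trace

        rec, _ = gen_transient_trace(TransientSimSpec(seed=11))
        train = beats.detect_stimuli(rec)
        assert len(train.segments) == 7
        np.testing.assert_allclose(
            train.segments["frequency_hz"],
            [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0],
            rtol=0.05,
        )


class TestEstimateNoise:
    def test_zero_signal_gives_zero(self, short_trace):
        rec, _ = short_trace
        train = beats.detect_stimuli(rec)
        est = beats.estimate_noise(np.zeros(rec.n_samples), train, rec.sampling_rate)
        assert est.a_noise == 0.0

    def test_matches_bruteforce_window_maximum(self, short_trace, rng):
        rec, _ = short_trace
        train = beats.detect_stimuli(rec)
        x = rng.normal(0, 1, rec.n_samples)
        est = beats.estimate_noise(x, train, rec.sampling_rate)
        # naive: max over every 200 ms window preceding stimuli at <=1 Hz
        expected = -np.inf
        for row in train.segments.itertuples():
            if row.frequency_hz > 1.0:
                continue
            for ts in train.stimulus_times[row.start : row.stop]:
                i1 = int(np.floor(ts * rec.sampling_rate))
                i0 = max(0, i1 - int(round(0.2 * rec.sampling_rate)))
                expected = max(expected, x[i0:i1].max())
        assert est.a_noise == expected

    def test_constant_window_value_recovered(self, short_trace):
        rec, _ = short_trace
        train = beats.detect_stimuli(rec)
        x = np.full(rec.n_samples, 0.07)
        est = beats.estimate_noise(x, train, rec.sampling_rate)
        assert est.a_noise == pytest.approx(0.07)

    def test_no_slow_interval_is_an_error(self):
        from cardiokit.synth import gen_transient_trace

        spec = TransientSimSpec(pacing_frequencies=(2.0, 3.0), seed=0)
        rec, _ = gen_transient_trace(spec)
        train = beats.detect_stimuli(rec)
        with pytest.raises(AnalysisError, match="a_noise"):
            beats.estimate_noise(np.zeros(rec.n_samples), train, rec.sampling_rate)


class TestAnalyzeBeats:
    def test_noise_free_metrics_match_generator_closed_form(self, clean_trace):
        spec, (rec, truth) = clean_trace
        _, per_beat, _ = beats.analyze_recording(rec, a_noise=0.01)
        m = truth.merge(per_beat, on="stimulus_time_s", suffixes=("_t", ""))
        cap = m[m["captured_t"] & m["decay_resolved"]]
        assert (cap["captured"]).all()
        np.testing.assert_allclose(cap["amplitude"], cap["amplitude_t"], rtol=0.01)
        dt = 1.0 / rec.sampling_rate
        assert (cap["ttp90_s"] - cap["ttp90"]).abs().max() < 2 * dt
        assert (cap["ttbl90_s"] - cap["ttbl90"]).abs().max() < 2 * dt

    def test_peak_below_twice_noise_not_captured(self):
        """A beat 1.9x the noise amplitude above diastole fails the gate."""
        fs = 1000.0
        n = 3000
        x = np.zeros(n)
        k = 1500
        x[k - 50 : k + 150] = 1.9 * np.hanning(200)  # peak height 1.9 with a_noise=1
        train = beats.StimulusTrain(
            stimulus_times=np.array([1.4]),
            segments=pd.DataFrame([{"start": 0, "stop": 1, "frequency_hz": 1.0}]),
            trace_end_s=3.0,
        )
        noise = beats.NoiseEstimate(a_noise=1.0)
        out = beats.analyze_beats(x, train, noise, fs)
        assert not out["captured"].iloc[0]
        out2 = beats.analyze_beats(2.2 * x, train, noise, fs)
        assert out2["captured"].iloc[0]

    def test_catd_is_exactly_ttp_plus_ttbl(self, short_trace):
        rec, _ = short_trace
        _, per_beat, _ = beats.analyze_recording(rec)
        cap = per_beat[per_beat["captured"] & per_beat["decay_resolved"]]
        assert len(cap) > 10
        np.testing.assert_array_equal(
            cap["catd90_s"].to_numpy(), (cap["ttp90_s"] + cap["ttbl90_s"]).to_numpy()
        )


class TestSummarizeInterval:
    @staticmethod
    def _beats_frame(amplitudes, captured=None):
        n = len(amplitudes)
        captured = [True] * n if captured is None else captured
        return pd.DataFrame(
            {
                "captured": captured,
                "diastolic_level": np.zeros(n),
                "amplitude": amplitudes,
                "ttp90_s": np.full(n, 0.02),
                "ttbl90_s": np.full(n, 0.1),
                "catd90_s": np.full(n, 0.12),
            }
        )

    def test_identical_beats_reproduce_single_beat_metrics(self):
        out = beats.summarize_interval(self._beats_frame([0.5] * 24), 1.0)
        assert out["n_beats_used"] == 6
        assert out["amplitude"] == pytest.approx(0.5)

    def test_last_six_of_ascending_amplitudes(self):
        """Amplitudes 1..24 -> mean of 19..24 = 21.5."""
        out = beats.summarize_interval(self._beats_frame(list(range(1, 25))), 1.0)
        assert out["amplitude"] == pytest.approx(21.5)

    def test_fewer_captured_beats_recorded(self):
        frame = self._beats_frame([1.0, 2.0, 3.0], captured=[True, True, True])
        out = beats.summarize_interval(frame, 2.0)
        assert out["n_beats_used"] == 3

    def test_zero_captured_marks_frequency_not_captured(self):
        frame = self._beats_frame([np.nan], captured=[False])
        out = beats.summarize_interval(frame, 4.0)
        assert out["captured"] is False


class TestSarcomereLength:
    def test_noise_free_sinusoid_recovered(self):
        x, prof = gen_striation_profile(sl_um=1.8, noise_sd=0.0)
        assert beats.estimate_sarcomere_length(prof, x[1] - x[0]) == pytest.approx(
            1.8, abs=0.02
        )

    def test_white_noise_raises_diagnostic(self, rng):
        prof = rng.normal(0, 1, 600)
        with pytest.raises(AnalysisError, match="background"):
            beats.estimate_sarcomere_length(prof, 0.05)

    def test_periods_ordered_correctly(self):
        vals = []
        for sl in (1.7, 1.9):
            x, prof = gen_striation_profile(sl_um=sl, noise_sd=0.05, seed=4)
            vals.append(beats.estimate_sarcomere_length(prof, x[1] - x[0]))
        assert vals[0] < vals[1]
        assert vals[0] == pytest.approx(1.7, abs=0.05)
        assert vals[1] == pytest.approx(1.9, abs=0.05)

    def test_sarcomere_trace_amplitudes_recovered(self):
        spec = TransientSimSpec(
            pacing_frequencies=(1.0, 2.0), noise_sd=0.003, missed_beat_prob=0.0, seed=9
        )
        rec, truth = gen_sarcomere_trace(spec, resting_sl_um=1.8, shortening_um=0.1)
        _, per_beat, _ = beats.analyze_recording(
            rec, channel="sarcomere_length", invert=True
        )
        m = truth.merge(per_beat, on="stimulus_time_s", suffixes=("_t", ""))
        cap = m[m["captured_t"] & m["captured"]]
        assert len(cap) / len(m) > 0.95
        assert (cap["amplitude"] / cap["amplitude_t"] - 1).abs().mean() < 0.03
        np.testing.assert_allclose(cap["diastolic_level"], 1.8, atol=0.01)


class TestPipelineInvariances:
    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(offset=st.floats(-3.0, 3.0))
    def test_translation_moves_only_the_diastolic_level(self, offset):
        spec = TransientSimSpec(
            pacing_frequencies=(1.0,), min_stimuli=6, min_duration_s=0.0, seed=21
        )
        from cardiokit.synth import gen_transient_trace

        rec, _ = gen_transient_trace(spec)
        base_noise, base, _ = beats.analyze_recording(rec)
        shifted = TimeSeriesRecording(
            time=rec.time,
            channels={
                "fura_ratio": rec.channels["fura_ratio"] + offset,
                "stimulus": rec.channels["stimulus"],
            },
            sampling_rate=rec.sampling_rate,
        )
        s_noise, shifted_beats, _ = beats.analyze_recording(shifted)
        assert s_noise.a_noise == pytest.approx(base_noise.a_noise, abs=1e-9)
        pd.testing.assert_series_equal(base["captured"], shifted_beats["captured"])
        np.testing.assert_allclose(
            shifted_beats["amplitude"], base["amplitude"], atol=1e-9
        )
        cap = base["captured"]
        np.testing.assert_allclose(
            shifted_beats.loc[cap, "diastolic_level"],
            base.loc[cap, "diastolic_level"] + offset,
            atol=1e-9,
        )

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(scale=st.floats(0.2, 5.0))
    def test_amplitude_scale_equivariance(self, scale):
        spec = TransientSimSpec(
            pacing_frequencies=(1.0,), min_stimuli=6, min_duration_s=0.0, seed=22
        )
        from cardiokit.synth import gen_transient_trace

        rec, _ = gen_transient_trace(spec)
        _, base, _ = beats.analyze_recording(rec)
        scaled_rec = TimeSeriesRecording(
            time=rec.time,
            channels={
                "fura_ratio": rec.channels["fura_ratio"] * scale,
                "stimulus": rec.channels["stimulus"],
            },
            sampling_rate=rec.sampling_rate,
        )
        _, scaled, _ = beats.analyze_recording(scaled_rec)
        pd.testing.assert_series_equal(base["captured"], scaled["captured"])
        np.testing.assert_allclose(
            scaled["amplitude"], base["amplitude"] * scale, rtol=1e-7
        )
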