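"""EEG analysis: filtering, spectrograms, baseline correction, t-map
clusters, the RMS spindle detector, probability timecourses, and the
set-size mixed models."""

import numpy as np
import pandas as pd
import pytest

from multicue.design import CueEvent, CueSchedule
from multicue.eeg import (
    SpindleDetectorConfig,
    SpindleEvent,
    TFCluster,
    bandpass,
    baseline_correct,
    cluster_power,
    cluster_tmap,
    detect_spindles,
    epoch_and_spectrogram,
    fit_memory_physiology_lmm,
    fit_setsize_lmm,
    moving_rms,
    per_trial_spindle_metrics,
    spindle_probability_timecourse,
)
from multicue.eegsim import EegRecording, synthesize_background

FS = 512.0


def sinusoid(freq, dur=20.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_amplitude_retained(self):
        for f in (11.0, 13.0, 16.0):
            y = bandpass(sinusoid(f), FS, 11, 16)
            assert np.abs(y[int(5 * FS): int(15 * FS)]).max() >= 0.95

    def test_out_of_band_attenuated(self):
        y = bandpass(sinusoid(5.0), FS, 11, 16)
        assert np.abs(y[int(5 * FS): int(15 * FS)]).max() <= 0.1

    def test_zero_signal_stays_zero(self):
        assert not bandpass(np.zeros(4096), FS, 11, 16).any()

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(1024), 128.0, 11, 70)


@pytest.fixture()
def spec_recording():
    rng = np.random.default_rng(0)
    x = 0.1 * rng.standard_normal(int(60 * FS))
    t = np.arange(len(x)) / FS
    x += np.sin(2 * np.pi * 10.0 * t)
    events = [
        CueEvent(sound_id=f"s{i}", size_k=2, onset_s=5.0 + 10.0 * i, pass_idx=0, rep_idx=i, iti_s=5.0)
        for i in range(5)
    ]
    return EegRecording(samples=x, fs=FS, events=events)


class TestSpectrogram:
    def test_grid_matches_declared_resolution(self, spec_recording):
        spec = epoch_and_spectrogram(spec_recording)
        assert len(spec.freqs) == 100  # 0.25..25 in 0.25 steps
        assert spec.freqs[1] - spec.freqs[0] == pytest.approx(0.25)
        assert spec.times[1] - spec.times[0] == pytest.approx(0.0625)  # 62.5 ms hop
        assert spec.power.shape[0] == 5

    def test_pure_tone_peaks_at_its_bin(self, spec_recording):
        spec = epoch_and_spectrogram(spec_recording)
        mean_over_time = spec.power.mean(axis=(0, 2))
        assert spec.freqs[np.argmax(mean_over_time)] == pytest.approx(10.0)

    def test_zero_epoch_gives_zero_power(self):
        rec = EegRecording(
            samples=np.zeros(int(30 * FS)), fs=FS,
            events=[CueEvent("s", 1, 10.0, 0, 0, 5.0)],
        )
        spec = epoch_and_spectrogram(rec)
        assert not spec.power.any()

    def test_truncated_epochs_dropped_with_warning(self, caplog):
        rec = EegRecording(
            samples=np.random.default_rng(0).standard_normal(int(30 * FS)), fs=FS,
            events=[CueEvent("ok", 1, 10.0, 0, 0, 5.0), CueEvent("late", 1, 28.0, 0, 1, 5.0)],
        )
        with caplog.at_level("WARNING"):
            spec = epoch_and_spectrogram(rec)
        assert spec.power.shape[0] == 1
        assert any("truncated" in r.message for r in caplog.records)


class TestBaselineCorrect:
    def test_flat_power_corrects_to_zero(self):
        times = np.linspace(-0.25, 3.7, 64)
        P = np.full((10, 64), 7.0)
        out = baseline_correct(P, times)
        assert np.allclose(out, 0.0)

    def test_doubling_gives_plus_hundred_percent(self):
        times = np.linspace(-0.25, 3.7, 64)
        P = np.full((4, 64), 3.0)
        P[:, times > 0] = 6.0
        out = baseline_correct(P, times)
        assert np.allclose(out[:, times > 0], 100.0)

    def test_correction_is_invertible(self, rng):
        times = np.linspace(-0.25, 3.7, 64)
        P = rng.uniform(1.0, 5.0, size=(8, 64))
        corr = baseline_correct(P, times)
        base = P[:, times <= -0.2].mean(axis=1)
        recovered = base[:, None] * (1.0 + corr / 100.0)
        assert np.allclose(recovered, P)

    def test_zero_baseline_rejected(self):
        times = np.linspace(-0.25, 3.7, 64)
        with pytest.raises(ValueError, match="zero baseline"):
            baseline_correct(np.zeros((2, 64)), times)

    def test_window_must_cover_a_column(self):
        times = np.linspace(0.5, 3.7, 32)
        with pytest.raises(ValueError, match="no spectrogram column"):
            baseline_correct(np.ones((2, 32)), times)


class TestClusterTmap:
    def test_pure_noise_rarely_clusters(self, rng):
        hits = 0
        times = np.linspace(-0.25, 3.7, 57)
        freqs = np.arange(0.25, 25.01, 0.25)
        for _ in range(50):
            maps = rng.standard_normal((12, len(freqs), len(times)))
            hits += bool(cluster_tmap(maps, times, freqs))
        assert hits == 0

    def test_recovers_injected_blob(self, rng):
        times = np.linspace(-0.25, 3.7, 57)
        freqs = np.arange(0.25, 25.01, 0.25)
        maps = rng.standard_normal((10, len(freqs), len(times)))
        fsel = (freqs >= 12) & (freqs <= 15)
        tsel = (times >= 1.0) & (times <= 1.4)
        maps[:, np.ix_(fsel, tsel)[0], np.ix_(fsel, tsel)[1]] += 6.0
        clusters = cluster_tmap(maps, times, freqs)
        assert clusters
        big = clusters[0]
        assert big.freq_lo <= freqs[fsel].min() and big.freq_hi >= freqs[fsel].max()
        assert big.t_lo <= times[tsel].min() and big.t_hi >= times[tsel].max()

    def test_all_zero_maps_give_no_clusters(self):
        times = np.linspace(-0.25, 3.7, 10)
        freqs = np.arange(1.0, 6.0)
        assert cluster_tmap(np.zeros((5, 5, 10)), times, freqs) == []

    def test_requires_three_participants(self):
        with pytest.raises(ValueError):
            cluster_tmap(np.zeros((2, 4, 4)), np.arange(4.0), np.arange(4.0))


class TestClusterPower:
    def _cluster(self, shape, sel=None):
        mask = np.zeros(shape, bool)
        mask[sel if sel is not None else np.s_[:, :]] = True
        return TFCluster(0, 1, 0, 1, mask=mask)

    def test_uniform_matrix(self):
        assert cluster_power(np.full((4, 6), 10.0), self._cluster((4, 6))) == 10.0

    def test_single_point_cluster(self):
        m = np.arange(24.0).reshape(4, 6)
        assert cluster_power(m, self._cluster((4, 6), (2, 3))) == m[2, 3]

    def test_checkerboard_cancels(self):
        m = np.indices((4, 6)).sum(axis=0) % 2 * 2.0 - 1.0
        assert cluster_power(m, self._cluster((4, 6))) == pytest.approx(0.0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_power(np.ones((2, 2)), TFCluster(0, 1, 0, 1, mask=np.zeros((2, 2), bool)))


class TestMovingRms:
    def test_constant_signal(self):
        out = moving_rms(np.full(1000, 3.0), FS, 0.2)
        assert np.allclose(out, 3.0)

    def test_matches_naive_loop_oracle(self, rng):
        x = rng.standard_normal(400)
        fs, w = 100.0, 0.1
        got = moving_rms(x, fs, w)
        half = int(round(w * fs / 2))
        for i in range(0, 400, 37):
            seg = x[max(0, i - half): min(len(x), i + half + 1)]
            assert got[i] == pytest.approx(np.sqrt((seg**2).mean()))


class TestDetectSpindles:
    def _with_burst(self, dur, freq=13.0, amp=8.0, seed=0):
        rec = synthesize_background(60.0, rng_seed=seed, noise_rms_uv=5.0, slow_osc_amp_uv=20.0)
        x = rec.samples.copy()
        i0 = int(30.0 * FS)
        n = int(dur * FS)
        t = np.arange(n) / FS
        x[i0: i0 + n] += amp * np.sin(2 * np.pi * freq * t)
        return x

    def test_zero_signal_yields_no_events(self):
        assert detect_spindles(np.zeros(int(10 * FS)), FS) == []

    def test_single_high_snr_burst_found_once(self):
        x = self._with_burst(1.0)
        events = detect_spindles(x, FS)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_s < 31.0 and ev.offset_s > 30.0
        assert 0.5 <= ev.duration_s <= 3.0

    def test_sub_minimum_burst_ignored(self):
        # a ramped 0.4-s burst at the generator's 3x RMS-ratio SNR spends
        # less than the 500-ms minimum above threshold and yields no event
        from multicue.eegsim import _burst

        rec = synthesize_background(60.0, rng_seed=0, noise_rms_uv=5.0, slow_osc_amp_uv=20.0)
        sigma = bandpass(rec.samples, FS, 11, 16).std()
        x = rec.samples.copy()
        i0 = int(30.0 * FS)
        b = _burst(FS, 13.0, 0.4, 3.0 * np.sqrt(2) * sigma, 0.0)
        x[i0: i0 + len(b)] += b
        events = detect_spindles(x, FS)
        assert all(not (29.5 < e.onset_s < 31.0) for e in events)

    def test_peak_amplitude_from_filtered_trace(self):
        x = self._with_burst(1.5, amp=10.0)
        ev = detect_spindles(x, FS)[0]
        assert ev.peak_amp_uv == pytest.approx(10.0, rel=0.3)

    def test_masked_region_excluded(self):
        x = self._with_burst(1.0)
        mask = np.zeros(len(x), bool)
        mask[int(29.0 * FS): int(32.0 * FS)] = True
        events = detect_spindles(x, FS, exclusion_mask=mask)
        assert all(not (29.0 < e.onset_s < 32.0) for e in events)

    def test_fully_masked_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            detect_spindles(np.zeros(int(5 * FS)), FS, exclusion_mask=np.ones(int(5 * FS), bool))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SpindleDetectorConfig(min_dur_s=3.0, max_dur_s=1.0)
        with pytest.raises(ValueError):
            SpindleDetectorConfig(threshold_mode="percentile")


class TestSpindleProbability:
    def _events(self, n=10, spacing=6.0):
        return [
            CueEvent(f"s{i}", 6 if i % 2 else 1, 10.0 + spacing * i, 0, i, 5.0)
            for i in range(n)
        ]

    def test_no_spindles_flat_zero(self):
        df, _ = spindle_probability_timecourse([], self._events())
        assert np.allclose(df["probability"], 0.0)

    def test_spindle_on_every_trial_gives_probability_one(self):
        events = self._events()
        spindles = [SpindleEvent(e.onset_s + 1.0, 0.5, 10.0) for e in events]
        df, _ = spindle_probability_timecourse(spindles, events)
        window = (df["time_s"] >= 1.05) & (df["time_s"] <= 1.45)
        assert np.allclose(df.loc[window, "probability"], 1.0)
        base = (df["time_s"] >= -0.5) & (df["time_s"] <= -0.2)
        assert np.allclose(df.loc[base, "probability"], 0.0)

    def test_per_trial_metrics(self):
        events = self._events(4)
        spindles = [SpindleEvent(events[0].onset_s + 1.0, 0.6, 12.0)]
        m = per_trial_spindle_metrics(spindles, events, (0.94, 1.44))
        assert m["spindle_present"].tolist() == [True, False, False, False]
        assert m.loc[0, "max_spindle_amp_uv"] == 12.0


def synth_trials(rng, slope, n_subj=5, n_sounds=12, reps=6, subj_sd=1.0, noise=3.0):
    rows = []
    sizes = [0, 1, 2, 6]
    for s in range(n_subj):
        intercept = rng.normal(scale=subj_sd)
        for snd in range(n_sounds):
            k = sizes[snd % 4]
            for r in range(reps):
                rows.append(
                    {
                        "participant_id": f"p{s}",
                        "sound_id": f"snd{snd}",
                        "set_size": k,
                        "modulation": intercept + slope * k + rng.normal(scale=noise),
                    }
                )
    return pd.DataFrame(rows)


class TestSetSizeLmm:
    def test_recovers_generator_slope(self, rng):
        df = synth_trials(rng, slope=2.0)
        res = fit_setsize_lmm(df)
        assert res.coef == pytest.approx(2.0, abs=0.5)
        assert res.ci_lo < 2.0 < res.ci_hi

    def test_zero_slope_ci_covers_zero_at_nominal_rate(self):
        rng = np.random.default_rng(7)
        cover = [
            (lambda r: r.ci_lo <= 0.0 <= r.ci_hi)(fit_setsize_lmm(synth_trials(rng, 0.0)))
            for _ in range(30)
        ]
        assert np.mean(cover) >= 0.8  # ~95% nominal, binomial slack at 30 reps

    def test_single_participant_reduces_to_ols(self, rng):
        df = synth_trials(rng, slope=1.5, n_subj=1)
        res = fit_setsize_lmm(df)
        assert res.structure == "ols"
        beta = np.polyfit(df["set_size"], df["modulation"], 1)[0]
        assert res.coef == pytest.approx(beta)


class TestMemoryPhysiologyLmm:
    def test_recovers_modulation_coefficient(self, rng):
        df = synth_trials(rng, slope=1.0)
        df["benefit"] = 0.5 * df["modulation"] + rng.normal(scale=1.0, size=len(df))
        res = fit_memory_physiology_lmm(df)
        assert res["modulation"].coef == pytest.approx(0.5, abs=0.15)

    def test_null_dependence_covers_zero(self, rng):
        df = synth_trials(rng, slope=1.0)
        df["benefit"] = rng.normal(size=len(df))
        res = fit_memory_physiology_lmm(df)
        assert res["modulation"].ci_lo <= 0.0 <= res["modulation"].ci_hi

    def test_constant_modulation_rejected(self, rng):
        df = synth_trials(rng, slope=0.0)
        df["modulation"] = 1.0
        df["benefit"] = rng.normal(size=len(df))
        with pytest.raises(ValueError, match="constant"):
            fit_memory_physiology_lmm(df)

    def test_empty_join_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_memory_physiology_lmm(
                pd.DataFrame(columns=["participant_id", "benefit", "modulation", "set_size"])
            )
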