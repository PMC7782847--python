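"""Synthetic single-channel NREM sleep EEG with cue-locked responses.

The generator produces a 1/f^α noise bed with a continuous slow
oscillation, then injects, at each cue onset, a delta-theta burst whose
amplitude grows linearly with the number of items associated with the cue,
and — probabilistically, with probability also linear in set size — one
sleep spindle (a Hann-enveloped 11–16 Hz burst lasting 0.5–3 s). The novel
sound counts as zero associated items. The injected linear laws are the
ground truth the analysis stack must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CueSchedule

__all__ = [
    "EegRecording",
    "EvokedResponseParams",
    "synthesize_background",
    "inject_cue_responses",
]

MIN_FS = 128.0  # > 2x the highest analysis frequency (25 Hz), with margin


@dataclass
class EegRecording:
    """Single-channel recording: ``samples`` in µV at ``fs`` Hz, cue
    ``events``, and an optional boolean ``artifact_mask`` (True = excluded)."""

    samples: np.ndarray
    fs: float
    events: list = field(default_factory=list)
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fs < MIN_FS:
            raise ValueError(f"fs must be >= {MIN_FS} Hz")
        dur = len(self.samples) / self.fs
        for e in self.events:
            if not 0.0 <= e.onset_s < dur:
                raise ValueError(f"event onset {e.onset_s}s outside recording (0-{dur:.1f}s)")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class EvokedResponseParams:
    """Ground-truth cue-response model.

    Spindle probability per cue is ``clip(spindle_prob_base +
    spindle_prob_per_item * k, 0, 1)``; delta-theta burst peak amplitude is
    ``deltatheta_amp_base + deltatheta_amp_per_item * k`` µV. Latency
    windows are seconds after cue onset; defaults place the delta-theta
    burst at 0.3–0.9 s and spindles at 0.9–1.4 s, the windows where evoked
    low-frequency and sigma activity concentrate after sounds in NREM
    sleep.
    """

    spindle_prob_base: float = 0.15
    spindle_prob_per_item: float = 0.05
    spindle_amp_uv: float = 25.0
    spindle_freq_range: tuple[float, float] = (11.0, 16.0)
    spindle_duration_range: tuple[float, float] = (0.5, 3.0)
    spindle_latency_window: tuple[float, float] = (0.9, 1.4)
    deltatheta_amp_base: float = 20.0
    deltatheta_amp_per_item: float = 2.0
    deltatheta_freq_range: tuple[float, float] = (2.0, 6.0)
    deltatheta_duration_range: tuple[float, float] = (0.4, 0.8)
    deltatheta_latency_window: tuple[float, float] = (0.3, 0.9)

    def __post_init__(self) -> None:
        lo, hi = self.spindle_duration_range
        if not (0.5 <= lo <= hi <= 3.0):
            raise ValueError("spindle durations must lie within [0.5, 3] s")

    def spindle_probability(self, size_k: int) -> float:
        return float(np.clip(self.spindle_prob_base + self.spindle_prob_per_item * size_k, 0.0, 1.0))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def synthesize_background(
    duration_s: float,
    fs: float = 512.0,
    rng_seed=None,
    noise_rms_uv: float = 15.0,
    slow_osc_amp_uv: float = 40.0,
    slow_osc_freq_hz: float = 0.8,
    alpha: float = 1.5,
) -> EegRecording:
    """Synthesize the NREM noise bed.

    Gaussian noise shaped to a 1/f^α spectrum (α ≈ 1.5, normalized to
    ``noise_rms_uv``) plus a continuous slow oscillation — narrowband
    Gaussian activity centered on ``slow_osc_freq_hz`` (±0.35 Hz), whose
    power is stationary across short analysis windows, unlike a pure tone.
    Zero mean; both amplitudes set to zero give an all-zero signal.
    Deterministic for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = _rng(rng_seed)
    n = int(round(duration_s * fs))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    if noise_rms_uv > 0:
        spec = np.fft.rfft(rng.standard_normal(n))
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-alpha / 2.0)
        x = np.fft.irfft(spec * shape, n=n)
        x *= noise_rms_uv / x.std()
    else:
        rng.standard_normal(n)  # keep the stream aligned across amp settings
        x = np.zeros(n)
    if slow_osc_amp_uv > 0:
        spec = np.fft.rfft(rng.standard_normal(n))
        bump = np.exp(-((f - slow_osc_freq_hz) ** 2) / (2 * 0.35**2))
        so = np.fft.irfft(spec * bump, n=n)
        # RMS matched to a sinusoid of the given amplitude
        so *= (slow_osc_amp_uv / np.sqrt(2.0)) / so.std()
        x = x + so
    else:
        rng.standard_normal(n)
    x -= x.mean()
    return EegRecording(samples=x, fs=fs)


def _burst(
    fs: float, freq: float, duration_s: float, amp: float, phase: float, ramp_frac: float = 0.5
) -> np.ndarray:
    """Ramped sinusoidal burst with the given peak amplitude.

    Tapered-cosine (Tukey) envelope: cosine ramps over ``ramp_frac`` of the
    burst (waxing-waning morphology) around a sustained core, so the burst's
    nominal duration matches the extent a threshold detector can see.
    """
    n = max(1, int(round(duration_s * fs)))
    t = np.arange(n) / fs
    env = _tukey(n, ramp_frac)
    return amp * env * np.sin(2 * np.pi * freq * t + phase)


def _tukey(n: int, alpha: float) -> np.ndarray:
    if n == 1:
        return np.ones(1)
    x = np.linspace(0.0, 1.0, n)
    env = np.ones(n)
    edge = alpha / 2.0
    lo = x < edge
    hi = x > 1.0 - edge
    env[lo] = 0.5 * (1 + np.cos(np.pi * (2 * x[lo] / alpha - 1)))
    env[hi] = 0.5 * (1 + np.cos(np.pi * (2 * (1 - x[hi]) / alpha - 1)))
    return env


def inject_cue_responses(
    recording: EegRecording,
    schedule: CueSchedule,
    params: EvokedResponseParams,
    rng_seed=None,
) -> tuple[EegRecording, pd.DataFrame]:
    """Inject cue-locked responses; returns (new recording, ground truth).

    Every cue receives a delta-theta burst whose amplitude scales linearly
    with the cue's set size; with the set-size-dependent probability it
    additionally receives one spindle (uniform frequency within the sigma
    band, uniform duration within the detector-compatible range, onset
    uniform within the latency window). Overlapping injections sum. The
    ground-truth table lists every injected spindle and burst with onset,
    duration, frequency and amplitude.
    """
    rng = _rng(rng_seed)
    x = recording.samples.copy()
    fs = recording.fs
    dur = recording.duration_s
    rows = []
    for e in schedule.events:
        if not 0.0 <= e.onset_s < dur:
            raise ValueError(f"cue onset {e.onset_s}s outside recording")
        k = e.size_k
        # delta-theta burst: always present
        f_dt = rng.uniform(*params.deltatheta_freq_range)
        d_dt = rng.uniform(*params.deltatheta_duration_range)
        lat_dt = rng.uniform(*params.deltatheta_latency_window)
        amp_dt = params.deltatheta_amp_base + params.deltatheta_amp_per_item * k
        b = _burst(fs, f_dt, d_dt, amp_dt, rng.uniform(0, 2 * np.pi))
        i0 = int(round((e.onset_s + lat_dt) * fs))
        seg = b[: max(0, len(x) - i0)]
        x[i0 : i0 + len(seg)] += seg
        rows.append(
            {
                "kind": "deltatheta",
                "sound_id": e.sound_id,
                "size_k": k,
                "cue_onset_s": e.onset_s,
                "onset_s": e.onset_s + lat_dt,
                "duration_s": d_dt,
                "freq_hz": f_dt,
                "amp_uv": amp_dt,
            }
        )
        if rng.uniform() < params.spindle_probability(k):
            f_sp = rng.uniform(*params.spindle_freq_range)
            d_sp = rng.uniform(*params.spindle_duration_range)
            lat_sp = rng.uniform(*params.spindle_latency_window)
            b = _burst(fs, f_sp, d_sp, params.spindle_amp_uv, rng.uniform(0, 2 * np.pi))
            i0 = int(round((e.onset_s + lat_sp) * fs))
            seg = b[: max(0, len(x) - i0)]
            x[i0 : i0 + len(seg)] += seg
            rows.append(
                {
                    "kind": "spindle",
                    "sound_id": e.sound_id,
                    "size_k": k,
                    "cue_onset_s": e.onset_s,
                    "onset_s": e.onset_s + lat_sp,
                    "duration_s": d_sp,
                    "freq_hz": f_sp,
                    "amp_uv": params.spindle_amp_uv,
                }
            )
    out = EegRecording(
        samples=x, fs=fs, events=list(schedule.events), artifact_mask=recording.artifact_mask
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "kind", "sound_id", "size_k", "cue_onset_s",
            "onset_s", "duration_s", "freq_hz", "amp_uv",
        ],
    )
    return out, truth
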