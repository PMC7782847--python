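"""Cue-locked sleep-EEG analysis.

The analysis chain mirrors standard event-related spectral analysis of
auditory cueing during NREM sleep: zero-phase FIR band-pass filtering;
cue-locked short-time-Fourier spectrograms (0.25–25 Hz in 0.25 Hz steps,
500-ms Hann windows with 87.5% overlap) expressed as percent power change
from a 300-ms pre-cue baseline; across-participant one-sample t-maps with
Bonferroni thresholding and connected-component cluster extraction;
per-trial mean modulation within a cluster; an RMS-threshold spindle
detector (11–16 Hz, 200-ms moving RMS, 1.5 SD threshold, 0.5–3 s duration
bounds); spindle probability timecourses by set size; and linear
mixed-effects models of the set-size modulation of per-trial responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy import stats as sps
import statsmodels.formula.api as smf

from .eegsim import EegRecording

__all__ = [
    "Spectrogram",
    "TFCluster",
    "SpindleEvent",
    "SpindleDetectorConfig",
    "LmmResult",
    "bandpass",
    "epoch_and_spectrogram",
    "baseline_correct",
    "cluster_tmap",
    "cluster_power",
    "detect_spindles",
    "moving_rms",
    "spindle_probability_timecourse",
    "per_trial_spindle_metrics",
    "fit_setsize_lmm",
    "fit_memory_physiology_lmm",
]

logger = logging.getLogger(__name__)


@dataclass
class Spectrogram:
    """Per-trial time-frequency power: ``power`` is (n_trials, n_freqs,
    n_times), times in seconds relative to cue onset (window centers)."""

    power: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    trial_index: pd.DataFrame | None = None  # sound_id / size_k per kept trial


@dataclass
class TFCluster:
    freq_lo: float
    freq_hi: float
    t_lo: float
    t_hi: float
    mask: np.ndarray = field(repr=False, default=None)  # (n_freqs, n_times)
    sign: int = 1


@dataclass(frozen=True)
class SpindleEvent:
    onset_s: float
    duration_s: float
    peak_amp_uv: float

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class SpindleDetectorConfig:
    """``threshold_mode`` selects the reference spread for the threshold:
    ``signal_sd`` (default) thresholds the RMS trace at ``threshold_sd``
    standard deviations of the band-passed signal; ``rms_sd`` uses the mean
    of the RMS trace plus ``threshold_sd`` of its standard deviations."""

    band: tuple[float, float] = (11.0, 16.0)
    rms_window_s: float = 0.2
    threshold_sd: float = 1.5
    min_dur_s: float = 0.5
    max_dur_s: float = 3.0
    threshold_mode: str = "signal_sd"

    def __post_init__(self) -> None:
        if not self.min_dur_s < self.max_dur_s:
            raise ValueError("min_dur_s must be < max_dur_s")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")
        if self.threshold_mode not in ("signal_sd", "rms_sd"):
            raise ValueError("threshold_mode must be 'signal_sd' or 'rms_sd'")


@dataclass
class LmmResult:
    term: str
    coef: float
    se: float
    ci_lo: float
    ci_hi: float
    tvalue: float
    df: int
    p: float
    structure: str  # which random-effects structure survived fitting
    extra: dict = field(default_factory=dict)


def bandpass(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Zero-phase FIR band-pass.

    A symmetric (linear-phase) Hamming-windowed FIR kernel applied by
    centered FFT convolution, so the output has no phase delay. The
    transition bands sit *outside* the requested [lo, hi] passband, so any
    in-band sinusoid (edges included) retains >=95% amplitude while
    attenuation one octave outside the band exceeds 20 dB.
    """
    if not 0 < lo_hz < hi_hz:
        raise ValueError("need 0 < lo_hz < hi_hz")
    if hi_hz >= fs / 2:
        raise ValueError(f"hi_hz={hi_hz} violates the Nyquist limit for fs={fs}")
    transition = min(lo_hz / 2.0, (hi_hz - lo_hz) / 2.0, (fs / 2.0 - hi_hz))
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    numtaps = min(numtaps, (len(x) // 2) * 2 - 1)
    cutoffs = [max(lo_hz - transition / 2.0, 1e-3), min(hi_hz + transition / 2.0, fs / 2.0 - 1e-3)]
    taps = signal.firwin(numtaps, cutoffs, pass_zero=False, fs=fs)
    return signal.fftconvolve(x, taps, mode="same")


def epoch_and_spectrogram(
    recording: EegRecording,
    events=None,
    epoch_window: tuple[float, float] = (-0.5, 4.0),
    window_s: float = 0.5,
    overlap_frac: float = 0.875,
    freq_lo: float = 0.25,
    freq_hi: float = 25.0,
    freq_step: float = 0.25,
) -> Spectrogram:
    """Cue-locked per-trial spectrograms.

    Epochs of ``epoch_window`` seconds around each cue onset are extracted,
    mean-subtracted, and transformed with a Hann short-time Fourier
    transform (500-ms windows, 87.5% overlap → 62.5-ms hop; zero-padding
    sets the frequency grid to ``freq_step`` spacing). Epochs extending
    beyond the recording are dropped with a warning. Power is one-sided
    spectral density per window; times are window centers relative to
    onset.
    """
    events = recording.events if events is None else events
    fs = recording.fs
    x = recording.samples
    nperseg = int(round(window_s * fs))
    noverlap = int(round(window_s * fs * overlap_frac))
    nfft = int(round(fs / freq_step))
    lo, hi = epoch_window
    n_epoch = int(round((hi - lo) * fs))

    powers, kept = [], []
    for e in events:
        i0 = int(round((e.onset_s + lo) * fs))
        i1 = i0 + n_epoch
        if i0 < 0 or i1 > len(x):
            logger.warning("dropping truncated epoch at %.2fs", e.onset_s)
            continue
        seg = x[i0:i1] - x[i0:i1].mean()
        f, t, S = signal.spectrogram(
            seg, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            nfft=nfft, detrend=False, mode="psd",
        )
        powers.append(S)
        kept.append({"sound_id": e.sound_id, "size_k": e.size_k, "onset_s": e.onset_s})
    if not powers:
        raise ValueError("no usable epochs")
    f_sel = (f >= freq_lo - 1e-9) & (f <= freq_hi + 1e-9)
    P = np.stack(powers)[:, f_sel, :]
    times = t + lo  # window centers relative to cue onset
    return Spectrogram(
        power=P, times=times, freqs=f[f_sel], trial_index=pd.DataFrame(kept)
    )


def baseline_correct(
    spec_power: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple[float, float] = (-0.5, -0.2),
    shared_baseline: bool = False,
) -> np.ndarray:
    """Percent power change relative to the pre-cue baseline.

    For each frequency, 100 · (P(t, f) − mean_baseline(f)) / mean_baseline(f),
    where the baseline mean runs over STFT windows centered inside
    ``baseline_window``. Works on a single (freq, time) matrix or a
    (trials, freq, time) stack; with ``shared_baseline`` the baseline
    spectrum is additionally averaged across trials (the common-baseline
    convention of event-related spectral perturbation analysis), which
    stabilizes single-trial modulations against the chi-squared noise of a
    one-window baseline estimate. Raises if the window covers no STFT
    column or any baseline power is zero.
    """
    P = np.asarray(spec_power, float)
    sel = (times >= baseline_window[0] - 1e-9) & (times <= baseline_window[1] + 1e-9)
    if not sel.any():
        raise ValueError("baseline window covers no spectrogram column")
    base = P[..., sel].mean(axis=-1)
    if shared_baseline and base.ndim == 2:
        base = np.broadcast_to(base.mean(axis=0), base.shape)
    if np.any(base == 0):
        raise ValueError("zero baseline power; percent change undefined")
    return 100.0 * (P - base[..., None]) / base[..., None]


def cluster_tmap(
    subject_maps: np.ndarray,
    times: np.ndarray,
    freqs: np.ndarray,
    alpha: float = 0.001,
    connectivity: int = 8,
) -> list[TFCluster]:
    """Bonferroni-thresholded t-map clusters across participants.

    One-sample t vs 0 at every time-frequency point of the per-participant
    mean corrected spectrograms (first axis = participants), thresholded at
    ``alpha / n_points``; contiguous threshold-crossers (8- or
    4-connectivity) of common sign become clusters with bounding
    time/frequency ranges. An empty list is a valid outcome.
    """
    maps = np.asarray(subject_maps, float)
    if maps.ndim != 3 or maps.shape[0] < 3:
        raise ValueError("need (n_subjects >= 3, n_freqs, n_times) maps")
    tstat, p = sps.ttest_1samp(maps, 0.0, axis=0)
    n_points = maps.shape[1] * maps.shape[2]
    sig = p < (alpha / n_points)
    structure = np.ones((3, 3)) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    clusters: list[TFCluster] = []
    for sign in (1, -1):
        lab, n_lab = ndimage.label(sig & (np.sign(tstat) == sign), structure=structure)
        for li in range(1, n_lab + 1):
            mask = lab == li
            fi, ti = np.nonzero(mask)
            clusters.append(
                TFCluster(
                    freq_lo=float(freqs[fi.min()]),
                    freq_hi=float(freqs[fi.max()]),
                    t_lo=float(times[ti.min()]),
                    t_hi=float(times[ti.max()]),
                    mask=mask,
                    sign=sign,
                )
            )
    clusters.sort(key=lambda c: -int(c.mask.sum()))
    return clusters


def cluster_power(trial_map: np.ndarray, cluster: TFCluster) -> float | np.ndarray:
    """Mean corrected power over a cluster's member points.

    ``trial_map`` is one (freq, time) matrix or a (trials, freq, time)
    stack; returns a scalar or per-trial vector accordingly.
    """
    if cluster.mask is None or not cluster.mask.any():
        raise ValueError("empty cluster")
    m = np.asarray(trial_map, float)
    if m.ndim == 2:
        return float(m[cluster.mask].mean())
    return m[:, cluster.mask].mean(axis=1)


def moving_rms(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Centered moving RMS with shrinking windows at the edges."""
    n = len(x)
    half = int(round(window_s * fs / 2))
    c = np.concatenate([[0.0], np.cumsum(np.asarray(x, float) ** 2)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n, i + half + 1)
    return np.sqrt((c[hi] - c[lo]) / (hi - lo))


def detect_spindles(
    x: np.ndarray,
    fs: float,
    config: SpindleDetectorConfig | None = None,
    exclusion_mask: np.ndarray | None = None,
) -> list[SpindleEvent]:
    """RMS-threshold spindle detection.

    The signal is band-passed to the sigma band, a centered 200-ms moving
    RMS is computed, and the RMS trace is thresholded at ``threshold_sd``
    standard deviations of the band-passed signal over included
    (artifact-free) samples (or of the RMS trace itself above its mean,
    with ``threshold_mode='rms_sd'``). Maximal runs that stay above
    threshold for 0.5–3 s and contain no excluded sample become events;
    each event's peak amplitude is the larger of the highest peak and
    |lowest trough| of the band-passed trace within the event.
    """
    config = config or SpindleDetectorConfig()
    x = np.asarray(x, float)
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask, bool)
        if excl.all():
            raise ValueError("all samples excluded")
    else:
        excl = np.zeros(len(x), bool)
    if len(x) < config.min_dur_s * fs:
        raise ValueError("signal shorter than the minimum spindle duration")
    filt = bandpass(x, fs, *config.band)
    rms = moving_rms(filt, fs, config.rms_window_s)
    if config.threshold_mode == "signal_sd":
        thr = config.threshold_sd * filt[~excl].std()
    else:
        thr = rms[~excl].mean() + config.threshold_sd * rms[~excl].std()
    above = (rms > thr) & ~excl
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(above)]])
    events = []
    for s, e in zip(starts, ends):
        dur = (e - s) / fs
        if config.min_dur_s <= dur <= config.max_dur_s:
            seg = filt[s:e]
            peak = max(seg.max(), -seg.min())
            events.append(SpindleEvent(onset_s=s / fs, duration_s=dur, peak_amp_uv=float(peak)))
    return events


def _ongoing_matrix(
    spindles: list[SpindleEvent],
    onsets: np.ndarray,
    rel_times: np.ndarray,
) -> np.ndarray:
    """(n_trials, n_times) indicator: a spindle is ongoing at onset + t."""
    out = np.zeros((len(onsets), len(rel_times)), bool)
    if spindles:
        sp_on = np.array([s.onset_s for s in spindles])
        sp_off = np.array([s.offset_s for s in spindles])
        abs_t = onsets[:, None] + rel_times[None, :]
        for on, off in zip(sp_on, sp_off):
            out |= (abs_t >= on) & (abs_t < off)
    return out


def spindle_probability_timecourse(
    spindles: list[SpindleEvent],
    cue_events,
    window: tuple[float, float] = (-0.5, 4.0),
    baseline_window: tuple[float, float] = (-0.5, -0.2),
    dt: float = 0.02,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Baseline-corrected spindle probability around cue onset, by set size.

    At each time point relative to onset, the probability is the fraction
    of trials during which a detected spindle is ongoing; the mean over the
    pre-cue baseline window is subtracted per size class. Size classes with
    zero trials are omitted with a warning. Returns a long DataFrame
    (size_k, time_s, probability) and the time grid.
    """
    rel_times = np.arange(window[0], window[1] + dt / 2, dt)
    onsets = np.array([e.onset_s for e in cue_events])
    sizes = np.array([e.size_k for e in cue_events])
    ongoing = _ongoing_matrix(spindles, onsets, rel_times)
    base_sel = (rel_times >= baseline_window[0] - 1e-9) & (rel_times <= baseline_window[1] + 1e-9)
    rows = []
    for k in sorted(set(sizes)):
        trials = ongoing[sizes == k]
        if len(trials) == 0:
            warnings.warn(f"size class {k} has zero trials; omitted")
            continue
        trace = trials.mean(axis=0)
        trace = trace - trace[base_sel].mean()
        rows.append(pd.DataFrame({"size_k": k, "time_s": rel_times, "probability": trace}))
    return pd.concat(rows, ignore_index=True), rel_times


def per_trial_spindle_metrics(
    spindles: list[SpindleEvent],
    cue_events,
    window: tuple[float, float],
) -> pd.DataFrame:
    """Per-trial spindle presence and max amplitude within a post-cue window
    (typically the sigma cluster's timeframe)."""
    rows = []
    for e in cue_events:
        t0, t1 = e.onset_s + window[0], e.onset_s + window[1]
        hits = [s for s in spindles if s.onset_s < t1 and s.offset_s > t0]
        rows.append(
            {
                "sound_id": e.sound_id,
                "size_k": e.size_k,
                "onset_s": e.onset_s,
                "spindle_present": bool(hits),
                "max_spindle_amp_uv": max((s.peak_amp_uv for s in hits), default=np.nan),
            }
        )
    return pd.DataFrame(rows)


def _mixedlm_ladder(formula_dv: str, fixed: str, data: pd.DataFrame, re_col: str):
    """Fit MixedLM with decreasing random-effects complexity.

    Ladder: random intercept + slope with a sound variance component →
    without the sound component → intercept only → plain OLS. Returns
    (fitted model or OLS result, structure label).
    """
    attempts = [
        ("intercept+slope+sound", dict(re_formula=f"~{re_col}", vc_formula={"sound": "0 + C(sound_id)"})),
        ("intercept+slope", dict(re_formula=f"~{re_col}")),
        ("intercept", dict(re_formula="~1")),
    ]
    for label, kw in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm(
                    f"{formula_dv} ~ {fixed}", data=data, groups=data["participant_id"], **kw
                )
                fit = md.fit(reml=False, method="lbfgs", maxiter=200)
            if np.isfinite(fit.params).all() and np.isfinite(fit.bse).all():
                return fit, label
        except Exception:  # singular / convergence / linalg failures fall through
            continue
    fit = smf.ols(f"{formula_dv} ~ {fixed}", data=data).fit()
    return fit, "ols"


def _extract_term(fit, structure: str, term: str, n_obs: int, n_fixed: int) -> LmmResult:
    coef = float(fit.params[term])
    se = float(fit.bse[term])
    df = n_obs - n_fixed
    tval = coef / se if se > 0 else np.inf
    p = float(2 * sps.t.sf(abs(tval), df))
    ci = fit.conf_int().loc[term]
    return LmmResult(
        term=term, coef=coef, se=se, ci_lo=float(ci[0]), ci_hi=float(ci[1]),
        tvalue=float(tval), df=df, p=p, structure=structure,
    )


def fit_setsize_lmm(data: pd.DataFrame, response: str = "modulation") -> LmmResult:
    """Linear mixed model of a per-trial response on set size.

    ``response ~ 1 + set_size`` with by-participant random intercept and
    set-size slope and a by-sound variance component; set size is numeric
    (0 for the novel sound, else the item count), so the coefficient is the
    change in response per additional associated item. The random-effects
    structure is simplified when the data cannot support it (down to OLS
    for a single participant, where the slope equals the OLS slope).
    """
    df = data.dropna(subset=[response, "set_size"]).copy()
    if df["participant_id"].nunique() < 1 or len(df) < 3:
        raise ValueError("not enough data for the set-size model")
    if df["participant_id"].nunique() == 1:
        fit = smf.ols(f"{response} ~ set_size", data=df).fit()
        return _extract_term(fit, "ols", "set_size", len(df), 2)
    fit, structure = _mixedlm_ladder(response, "set_size", df, "set_size")
    return _extract_term(fit, structure, "set_size", len(df), 2)


def fit_memory_physiology_lmm(data: pd.DataFrame) -> dict[str, LmmResult]:
    """Mixed model of per-item memory benefit on physiological modulation.

    ``benefit ~ 1 + modulation × set_size`` with a by-participant random
    modulation slope; returns results for the modulation main effect and
    the modulation × set-size interaction. ``data`` joins the behavioral
    (per-item benefit) and EEG (per-sound mean modulation) tables by
    participant and sound; an empty join or a constant modulation raises.
    """
    df = data.dropna(subset=["benefit", "modulation", "set_size"]).copy()
    if df.empty:
        raise ValueError("empty behavioral-physiological join")
    if np.ptp(df["modulation"].to_numpy(float)) == 0:
        raise ValueError("constant modulation; predictor carries no information")
    if df["participant_id"].nunique() == 1:
        fit = smf.ols("benefit ~ modulation * set_size", data=df).fit()
        structure = "ols"
    else:
        fit, structure = _mixedlm_ladder("benefit", "modulation * set_size", df, "modulation")
    n_fixed = 4
    return {
        "modulation": _extract_term(fit, structure, "modulation", len(df), n_fixed),
        "modulation:set_size": _extract_term(
            fit, structure, "modulation:set_size", len(df), n_fixed
        ),
    }
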