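"""Speech preprocessing and the 49-feature acoustic + rhythmic bank.

The bank summarizes how a participant speaks during a scene-description
task, not what they say (the transcript contributes only its character
count):

* 28 contour summaries: min, max, range, mean, std, skewness and excess
  kurtosis of the first three formant tracks (F1, F2, F3) and the pitch
  (F0) track, over voiced frames;
* 5 jitter measures (local, local absolute, rap, ppq5, ddp) -- normalized
  cycle-to-cycle perturbations of the pitch period;
* 12 duration summaries: min, max, range, mean, sum and std of the pause
  durations and of the per-interval effective speech durations;
* 4 rhythm ratios: long-pause/speech-count ratio, short-pause/speech-count
  ratio, total transcript characters, and articulation rate (characters
  per second of effective speech).

Pauses are silent gaps between speech intervals found by an energy-based
voice activity detector; pauses shorter than 1 s are classed "short"
(within-sentence), longer ones "long" (between-sentence).  Features that
cannot be measured on a given recording (e.g. jitter with too few voiced
periods) are reported as 0 with a quality flag, never dropped, so the
vector always has exactly 49 entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as spl
from scipy import stats as spst

from .cohort import AudioRecording, Transcript
from .features import FeatureVector

__all__ = [
    "FrameConfig",
    "VADConfig",
    "PitchConfig",
    "SpeechConfig",
    "Segmentation",
    "pre_emphasis",
    "frame_signal",
    "detect_segments",
    "pitch_contour",
    "formant_contours",
    "jitter_measures",
    "summarize_contour",
    "summarize_durations",
    "rhythm_ratios",
    "extract_speech_features",
    "speech_feature_names",
]

CONTOUR_STATS = ("min", "max", "range", "mean", "std", "skewness", "kurtosis")
DURATION_STATS = ("min", "max", "range", "mean", "sum", "std")
JITTER_KEYS = ("local", "local_absolute", "rap", "ppq5", "ddp")


@dataclass(frozen=True)
class FrameConfig:
    """Short-time analysis frames: 25 ms Hamming windows every 10 ms,
    preceded by first-order pre-emphasis."""

    frame_length_ms: float = 25.0
    hop_ms: float = 10.0
    window: str = "hamming"
    pre_emphasis: float = 0.97

    def __post_init__(self) -> None:
        if not (10.0 <= self.frame_length_ms <= 30.0):
            raise ValueError("frame length must lie in [10, 30] ms")
        if self.hop_ms > self.frame_length_ms:
            raise ValueError("hop must not exceed frame length")
        if not (0.0 <= self.pre_emphasis < 1.0):
            raise ValueError("pre-emphasis coefficient must be in [0, 1)")

    def frame_samples(self, fs: float) -> int:
        return int(round(self.frame_length_ms * fs / 1000.0))

    def hop_samples(self, fs: float) -> int:
        return int(round(self.hop_ms * fs / 1000.0))


@dataclass(frozen=True)
class VADConfig:
    """Energy-threshold voice activity detection.

    A frame is speech when its log energy exceeds the decision threshold

        max(silence_floor_db, min(noise floor + margin_db, peak - peak_headroom_db))

    where the noise floor is a low percentile of frame energies.  The
    peak-headroom cap keeps recordings that are speech throughout (noise
    floor = speech level) detectable, and the absolute silence floor (dB
    full scale) keeps an all-silent recording silent.  Gaps shorter than
    ``hangover_ms`` are smoothed over; silent gaps count as pauses only
    from ``min_pause_s`` up, and are classed long from ``long_pause_s``.
    """

    margin_db: float = 15.0
    noise_percentile: float = 5.0
    peak_headroom_db: float = 12.0
    silence_floor_db: float = -55.0
    #: VAD-specific short non-overlapping frames keep boundary bias within
    #: one hop (the spectral 25 ms frames would smear edges by ~30 ms)
    frame_ms: float = 10.0
    hop_ms: float = 10.0
    hangover_ms: float = 100.0
    min_speech_ms: float = 100.0
    min_pause_s: float = 0.15
    long_pause_s: float = 1.0


@dataclass(frozen=True)
class PitchConfig:
    """Autocorrelation pitch tracking over 40 ms frames."""

    fmin_hz: float = 60.0
    fmax_hz: float = 400.0
    frame_ms: float = 40.0
    hop_ms: float = 10.0
    voicing_threshold: float = 0.45  # normalized autocorrelation peak
    octave_tolerance: float = 0.85  # prefer shortest lag within this factor of the best peak


@dataclass(frozen=True)
class SpeechConfig:
    frames: FrameConfig = field(default_factory=FrameConfig)
    vad: VADConfig = field(default_factory=VADConfig)
    pitch: PitchConfig = field(default_factory=PitchConfig)
    formant_max_bandwidth_hz: float = 400.0
    formant_min_freq_hz: float = 90.0


@dataclass
class Segmentation:
    """Speech and pause intervals in seconds, ordered and non-overlapping.

    Leading and trailing silence belongs to neither list (edge policy);
    only gaps *between* speech intervals are pauses.
    """

    speech_intervals: list[tuple[float, float]]
    pause_intervals: list[tuple[float, float, str]]  # (start, end, "short"|"long")

    @property
    def effective_speech_durations(self) -> list[float]:
        return [e - s for s, e in self.speech_intervals]

    @property
    def pause_durations(self) -> list[float]:
        return [e - s for s, e, _ in self.pause_intervals]

    def pause_counts(self) -> dict[str, int]:
        counts = {"short": 0, "long": 0}
        for _, _, cls in self.pause_intervals:
            counts[cls] += 1
        return counts


# ---------------------------------------------------------------------------
# Preprocessing


def pre_emphasis(x: np.ndarray, alpha: float = 0.97) -> np.ndarray:
    """First-order high-pass y[n] = x[n] - alpha*x[n-1] (y[0] = x[0])."""
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must be in [0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return y


def frame_signal(x: np.ndarray, fs: float, cfg: FrameConfig | None = None) -> np.ndarray:
    """Slice into overlapping Hamming-windowed frames, shape (n_frames, L).

    Frame count is floor((N - L) / H) + 1; trailing samples that do not
    fill a frame are dropped.
    """
    cfg = cfg or FrameConfig()
    x = np.asarray(x, dtype=float)
    L, H = cfg.frame_samples(fs), cfg.hop_samples(fs)
    if x.size < L:
        raise ValueError(f"signal of {x.size} samples shorter than one {L}-sample frame")
    n_frames = (x.size - L) // H + 1
    idx = np.arange(L)[None, :] + H * np.arange(n_frames)[:, None]
    return x[idx] * np.hamming(L)


def _frame_starts(n: int, L: int, H: int) -> np.ndarray:
    return H * np.arange((n - L) // H + 1)


# ---------------------------------------------------------------------------
# Voice activity / pause segmentation


def detect_segments(
    x: np.ndarray, fs: float, cfg: SpeechConfig | None = None
) -> Segmentation:
    """Energy-based speech/pause segmentation.

    Per-frame log energy is thresholded at noise floor + margin; the
    binary decision is smoothed (gaps shorter than the hangover filled,
    blips shorter than ``min_speech_ms`` removed) and converted to
    intervals.  Gaps of at least ``min_pause_s`` between speech intervals
    become pauses; shorter gaps are absorbed into speech.
    """
    cfg = cfg or SpeechConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    vad = cfg.vad
    L = int(round(vad.frame_ms * fs / 1000.0))
    H = int(round(vad.hop_ms * fs / 1000.0))
    if x.size < L:
        warnings.warn("signal shorter than one frame; no speech detected", stacklevel=2)
        return Segmentation([], [])

    starts = _frame_starts(x.size, L, H)
    frames = x[starts[:, None] + np.arange(L)[None, :]]
    energy_db = 10.0 * np.log10(np.mean(frames**2, axis=1) + 1e-12)
    floor = np.percentile(energy_db, vad.noise_percentile)
    threshold = max(
        vad.silence_floor_db,
        min(floor + vad.margin_db, energy_db.max() - vad.peak_headroom_db),
    )
    speech = energy_db > threshold
    if not speech.any():
        warnings.warn("no frames above the energy threshold; all-silent input",
                      stacklevel=2)
        return Segmentation([], [])

    hang = max(1, int(round(vad.hangover_ms / vad.hop_ms)))
    speech = _fill_gaps(speech, hang)
    speech = _remove_runs(speech, max(1, int(round(vad.min_speech_ms / vad.hop_ms))))
    min_pause_frames = max(1, int(round(vad.min_pause_s * 1000.0 / vad.hop_ms)))
    speech = _fill_gaps(speech, min_pause_frames - 1)
    if not speech.any():
        return Segmentation([], [])

    # frame index spans -> time intervals (end = last frame start + frame length)
    intervals = []
    for a, b in _runs(speech):
        intervals.append((starts[a] / fs, (starts[b - 1] + L) / fs))
    pauses = []
    for (s0, e0), (s1, _) in zip(intervals[:-1], intervals[1:]):
        dur = s1 - e0
        if dur >= vad.min_pause_s:
            cls = "long" if dur >= vad.long_pause_s else "short"
            pauses.append((e0, s1, cls))
    return Segmentation(intervals, pauses)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index spans of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _fill_gaps(mask: np.ndarray, max_gap: int) -> np.ndarray:
    if max_gap <= 0:
        return mask
    out = mask.copy()
    inv_runs = _runs(~mask)
    for a, b in inv_runs:
        if a > 0 and b < mask.size and (b - a) <= max_gap:
            out[a:b] = True
    return out


def _remove_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = mask.copy()
    for a, b in _runs(mask):
        if (b - a) < min_len:
            out[a:b] = False
    return out


# ---------------------------------------------------------------------------
# Pitch


def pitch_contour(
    x: np.ndarray, fs: float, cfg: PitchConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation F0 track; returns (frame times, F0 Hz) for voiced frames.

    A frame is voiced when the strongest normalized autocorrelation peak in
    the candidate lag range exceeds the voicing threshold.  Among peaks
    within ``octave_tolerance`` of the best one, the shortest lag wins,
    which suppresses octave-down errors on strongly periodic frames.  The
    winning lag is refined by parabolic interpolation.
    """
    cfg = cfg or PitchConfig()
    x = np.asarray(x, dtype=float)
    L = int(round(cfg.frame_ms * fs / 1000.0))
    H = int(round(cfg.hop_ms * fs / 1000.0))
    lag_min = int(np.floor(fs / cfg.fmax_hz))
    lag_max = int(np.ceil(fs / cfg.fmin_hz))
    if x.size < L or L <= lag_max:
        return np.array([]), np.array([])

    starts = _frame_starts(x.size, L, H)
    frames = x[starts[:, None] + np.arange(L)[None, :]]
    frames = frames - frames.mean(axis=1, keepdims=True)
    # batched autocorrelation via FFT (linear, not circular)
    nfft = 1 << int(np.ceil(np.log2(2 * L)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, : lag_max + 2]
    r0 = ac[:, 0]
    valid = r0 > 0
    ac = ac / np.where(valid, r0, 1.0)[:, None]

    seg = ac[:, lag_min : lag_max + 1]
    inner = seg[:, 1:-1]
    is_peak = np.zeros_like(seg, dtype=bool)
    is_peak[:, 1:-1] = (inner > seg[:, :-2]) & (inner >= seg[:, 2:])
    peak_vals = np.where(is_peak, seg, -np.inf)
    best = peak_vals.max(axis=1)
    voiced = valid & (best >= cfg.voicing_threshold)
    # shortest candidate lag within the octave tolerance of the best peak
    cand = is_peak & (seg >= cfg.octave_tolerance * best[:, None])
    lag_idx = cand.argmax(axis=1) + lag_min

    times, f0s = [], []
    for i in np.flatnonzero(voiced):
        lag_f = _parabolic_refine(ac[i], int(lag_idx[i]))
        times.append((starts[i] + L / 2) / fs)
        f0s.append(fs / lag_f)
    return np.asarray(times), np.asarray(f0s)


def _local_maxima(y: np.ndarray) -> np.ndarray:
    if y.size < 3:
        return np.array([], dtype=int)
    return np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


# ---------------------------------------------------------------------------
# Formants


def formant_contours(
    x: np.ndarray,
    fs: float,
    cfg: SpeechConfig | None = None,
    voiced_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-frame F1/F2/F3 by linear-prediction root finding.

    The pre-emphasized, Hamming-windowed frame is fit with an all-pole
    model of order 2 + fs/1000 (autocorrelation method, Levinson
    recursion); pole angles give candidate resonance frequencies, kept
    when the implied bandwidth is below 400 Hz.  Frames with fewer than
    three surviving resonances are skipped and counted.

    Returns (times, formants[n, 3], n_skipped); each emitted row satisfies
    F1 < F2 < F3.  ``voiced_times`` (e.g. from :func:`pitch_contour`)
    restricts analysis to frames whose centre lies within 25 ms of a
    voiced pitch frame.
    """
    cfg = cfg or SpeechConfig()
    fr = cfg.frames
    x = pre_emphasis(np.asarray(x, dtype=float), fr.pre_emphasis)
    L, H = fr.frame_samples(fs), fr.hop_samples(fs)
    order = 2 + int(round(fs / 1000.0))
    if x.size < L:
        return np.array([]), np.empty((0, 3)), 0

    starts = _frame_starts(x.size, L, H)
    centers = (starts + L / 2) / fs
    if voiced_times is not None:
        if voiced_times.size == 0:
            return np.array([]), np.empty((0, 3)), 0
        near = np.abs(centers[:, None] - voiced_times[None, :]).min(axis=1) <= 0.025
        starts, centers = starts[near], centers[near]
    if starts.size == 0:
        return np.array([]), np.empty((0, 3)), 0
    frames = x[starts[:, None] + np.arange(L)[None, :]] * np.hamming(L)
    # batched autocorrelation for the Levinson recursions
    nfft = 1 << int(np.ceil(np.log2(2 * L)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    rr = np.fft.irfft(np.abs(spec) ** 2, nfft, axis=1)[:, : order + 1]

    times, rows, skipped = [], [], 0
    for i, t in enumerate(centers):
        if rr[i, 0] <= 0:
            skipped += 1
            continue
        try:
            coeffs = spl.solve_toeplitz((rr[i, :-1], rr[i, :-1]), -rr[i, 1:])
        except np.linalg.LinAlgError:
            skipped += 1
            continue
        a = np.concatenate(([1.0], coeffs))
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * fs / (2 * np.pi)
        with np.errstate(divide="ignore"):
            bws = -np.log(np.maximum(np.abs(roots), 1e-12)) * fs / np.pi
        keep = (
            (freqs > cfg.formant_min_freq_hz)
            & (freqs < fs / 2 - 50.0)
            & (bws < cfg.formant_max_bandwidth_hz)
        )
        cand = np.sort(freqs[keep])
        if cand.size < 3:
            skipped += 1
            continue
        times.append(t)
        rows.append(cand[:3])
    return np.asarray(times), np.asarray(rows).reshape(-1, 3), skipped


# ---------------------------------------------------------------------------
# Jitter


def jitter_measures(periods: np.ndarray) -> dict[str, float]:
    """Five standard pitch-period perturbation measures.

    With T_1..T_N the consecutive voiced period lengths (seconds) and
    Tbar their mean:

    * ``local_absolute`` = mean_i |T_i - T_{i-1}|               (seconds)
    * ``local``          = local_absolute / Tbar                (ratio)
    * ``rap``            = mean_i |T_i - mean(T_{i-1},T_i,T_{i+1})| / Tbar
    * ``ppq5``           = mean_i |T_i - mean(T_{i-2}..T_{i+2})| / Tbar
    * ``ddp``            = mean_i |(T_{i+1}-T_i) - (T_i-T_{i-1})| / Tbar

    ddp equals exactly 3*rap (the rap deviation is one third of the
    second difference), and is computed as such so the identity holds to
    the last bit.
    """
    T = np.asarray(periods, dtype=float)
    if T.size < 5:
        raise ValueError(f"need >= 5 consecutive periods, got {T.size}")
    if np.any(T <= 0):
        raise ValueError("periods must be positive")
    mean_T = T.mean()
    abs_diff = np.abs(np.diff(T))
    local_absolute = float(abs_diff.mean())
    second_diff = np.abs(T[2:] - 2 * T[1:-1] + T[:-2])
    rap = float(second_diff.mean() / 3.0 / mean_T)
    kernel = np.ones(5) / 5.0
    dev5 = np.abs(T[2:-2] - np.convolve(T, kernel, mode="valid"))
    ppq5 = float(dev5.mean() / mean_T)
    return {
        "local": local_absolute / mean_T,
        "local_absolute": local_absolute,
        "rap": rap,
        "ppq5": ppq5,
        "ddp": 3.0 * rap,
    }


# ---------------------------------------------------------------------------
# Summaries and ratios


def summarize_contour(values: np.ndarray) -> tuple[dict[str, float], dict[str, str]]:
    """min/max/range/mean/std/skewness/kurtosis of a contour.

    std is the sample standard deviation (ddof=1); skewness and kurtosis
    are the standardized third/fourth central moments, kurtosis as excess.
    Empty input flags every stat; n < 2 flags the dispersion stats.
    """
    v = np.asarray(values, dtype=float)
    stats = dict.fromkeys(CONTOUR_STATS, 0.0)
    flags: dict[str, str] = {}
    if v.size == 0:
        return stats, dict.fromkeys(CONTOUR_STATS, "empty_contour")
    stats["min"] = float(v.min())
    stats["max"] = float(v.max())
    stats["range"] = stats["max"] - stats["min"]
    stats["mean"] = float(v.mean())
    if v.size < 2:
        for k in ("std", "skewness", "kurtosis"):
            flags[k] = "n_lt_2"
    else:
        stats["std"] = float(v.std(ddof=1))
        if stats["std"] == 0.0:
            flags["skewness"] = flags["kurtosis"] = "zero_variance"
        else:
            stats["skewness"] = float(spst.skew(v, bias=True))
            stats["kurtosis"] = float(spst.kurtosis(v, fisher=True, bias=True))
    return stats, flags


def summarize_durations(values: list[float]) -> tuple[dict[str, float], dict[str, str]]:
    """min/max/range/mean/sum/std of a duration series (pauses or speech)."""
    v = np.asarray(values, dtype=float)
    stats = dict.fromkeys(DURATION_STATS, 0.0)
    flags: dict[str, str] = {}
    if v.size == 0:
        return stats, dict.fromkeys(DURATION_STATS, "empty_series")
    stats["min"] = float(v.min())
    stats["max"] = float(v.max())
    stats["range"] = stats["max"] - stats["min"]
    stats["mean"] = float(v.mean())
    stats["sum"] = float(v.sum())
    if v.size < 2:
        flags["std"] = "n_lt_2"
    else:
        stats["std"] = float(v.std(ddof=1))
    return stats, flags


def rhythm_ratios(
    seg: Segmentation, transcript: Transcript
) -> tuple[dict[str, float], dict[str, str]]:
    """Pause/speech-count ratios, transcript character count, articulation rate.

    Ratios divide the number of long (resp. short) pauses by the number of
    speech intervals; articulation rate is counted characters per second
    of effective speech.  Zero speech intervals leaves the ratios and rate
    at 0, flagged.
    """
    flags: dict[str, str] = {}
    n_speech = len(seg.speech_intervals)
    counts = seg.pause_counts()
    chars = transcript.counted_characters
    values = {
        "ratio_long_pause_speech_counts": 0.0,
        "ratio_short_pause_speech_counts": 0.0,
        "total_characters": float(chars),
        "articulation_rate": 0.0,
    }
    if n_speech == 0:
        flags["ratio_long_pause_speech_counts"] = "no_speech_intervals"
        flags["ratio_short_pause_speech_counts"] = "no_speech_intervals"
        flags["articulation_rate"] = "no_speech_intervals"
        return values, flags
    values["ratio_long_pause_speech_counts"] = counts["long"] / n_speech
    values["ratio_short_pause_speech_counts"] = counts["short"] / n_speech
    effective = sum(seg.effective_speech_durations)
    if effective > 0:
        values["articulation_rate"] = chars / effective
    else:
        flags["articulation_rate"] = "zero_effective_speech"
    if chars == 0:
        flags["total_characters"] = "empty_transcript"
    return values, flags


# ---------------------------------------------------------------------------
# The 49-feature bank


def speech_feature_names() -> list[str]:
    names = [f"{c}.{s}" for c in ("F1", "F2", "F3", "pitch") for s in CONTOUR_STATS]
    names += [f"jitter.{k}" for k in JITTER_KEYS]
    names += [
        f"{d}.{s}"
        for d in ("pause_time", "effective_speech_duration")
        for s in DURATION_STATS
    ]
    names += [
        "ratio_long_pause_speech_counts",
        "ratio_short_pause_speech_counts",
        "total_characters",
        "articulation_rate",
    ]
    return names


def extract_speech_features(
    audio: AudioRecording,
    transcript: Transcript,
    cfg: SpeechConfig | None = None,
) -> FeatureVector:
    """Compute the 49-feature bank for one recording + transcript.

    Pitch is tracked on the raw signal, formants on pre-emphasized frames
    restricted to voiced regions, jitter on the period sequence of the
    longest uninterrupted voiced run.  The schema is fixed: unmeasurable
    features are 0 with a flag.
    """
    cfg = cfg or SpeechConfig()
    x = np.asarray(audio.samples, dtype=float)
    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    seg = detect_segments(x, audio.fs, cfg)
    times, f0 = pitch_contour(x, audio.fs, cfg.pitch)
    # keep only pitch frames inside detected speech
    if times.size and seg.speech_intervals:
        in_speech = np.zeros(times.size, dtype=bool)
        for s, e in seg.speech_intervals:
            in_speech |= (times >= s) & (times <= e)
        times, f0 = times[in_speech], f0[in_speech]

    ftimes, formants, _ = formant_contours(x, audio.fs, cfg, voiced_times=times)
    for i, name in enumerate(("F1", "F2", "F3")):
        contour = formants[:, i] if formants.size else np.array([])
        stats, f = summarize_contour(contour)
        for k, v in stats.items():
            values[f"{name}.{k}"] = v
        for k, why in f.items():
            flags[f"{name}.{k}"] = why
    stats, f = summarize_contour(f0)
    for k, v in stats.items():
        values[f"pitch.{k}"] = v
    for k, why in f.items():
        flags[f"pitch.{k}"] = why

    periods = _longest_voiced_run_periods(times, f0, cfg.pitch)
    try:
        jit = jitter_measures(periods)
    except ValueError:
        jit = dict.fromkeys(JITTER_KEYS, 0.0)
        for k in JITTER_KEYS:
            flags[f"jitter.{k}"] = "too_few_voiced_periods"
    for k in JITTER_KEYS:
        values[f"jitter.{k}"] = jit[k]

    stats, f = summarize_durations(seg.pause_durations)
    for k, v in stats.items():
        values[f"pause_time.{k}"] = v
    for k, why in f.items():
        flags[f"pause_time.{k}"] = why
    stats, f = summarize_durations(seg.effective_speech_durations)
    for k, v in stats.items():
        values[f"effective_speech_duration.{k}"] = v
    for k, why in f.items():
        flags[f"effective_speech_duration.{k}"] = why

    ratios, f = rhythm_ratios(seg, transcript)
    values.update(ratios)
    flags.update(f)

    ordered = {n: values[n] for n in speech_feature_names()}
    return FeatureVector(ordered, flags)


def _longest_voiced_run_periods(
    times: np.ndarray, f0: np.ndarray, cfg: PitchConfig
) -> np.ndarray:
    """Period sequence (1/F0 per frame) of the longest gap-free voiced run."""
    if times.size == 0:
        return np.array([])
    max_gap = 2.5 * cfg.hop_ms / 1000.0
    breaks = np.flatnonzero(np.diff(times) > max_gap)
    segments = np.split(np.arange(times.size), breaks + 1)
    longest = max(segments, key=len)
    return 1.0 / f0[longest]


def write_segmentation(seg: Segmentation, path) -> None:
    """Audit writer: tab-separated (start, end, label) intervals."""
    with open(path, "w", encoding="utf-8") as fh:
        rows = [(s, e, "speech") for s, e in seg.speech_intervals] + [
            (s, e, f"pause_{cls}") for s, e, cls in seg.pause_intervals
        ]
        for s, e, label in sorted(rows):
            fh.write(f"{s:.3f}\t{e:.3f}\t{label}\n")
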