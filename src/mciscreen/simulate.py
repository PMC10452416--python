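"""Synthetic cohort generator with planted MCI group effects.

Real screening cohorts of this kind are not publicly shareable, so every
pipeline stage is exercised on a simulated cohort whose group differences
follow the directions reported for MCI speech and EEG:

* EEG: per-band band-limited Gaussian noise with controlled band powers;
  under the language task both groups show a low-frequency (delta/theta)
  power increase over rest, more pronounced in the MCI group.
* Speech: harmonic pulse-train "speech" bursts shaped by a fixed all-pole
  vocal-tract filter (so pitch, formants and jitter have exact ground
  truth), interleaved with silences.  The MCI group has a shorter total
  effective speech time, a lower share of short (within-sentence) pauses,
  fewer transcript characters, and a lower articulation rate.
* Digital parameters: MCI participants take longer to finish the test.

EEG band powers are set by FFT-masked noise scaled to an exact target
variance, making the planted spectral effects directly auditable; a
ground-truth sidecar JSON per participant records what was planted for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import (
    EEG_CHANNELS,
    AudioRecording,
    CohortManifest,
    DigitalParams,
    EEGRecording,
    Participant,
    write_audio,
    write_digital,
    write_eeg_csv,
    write_manifest,
)
from .eeg import DEFAULT_BANDS, BAND_ORDER

__all__ = ["EffectConfig", "generate_cohort", "generate_separable_toy", "generate_band_toy"]

#: Characters used to fill synthetic transcripts (cohort speaks Chinese).
_CHAR_POOL = "的一是了我不人在他有这上们来到时大地为子中你说生国年着就那和要她"

_LEFT_CHANNELS = ("TP9", "AF7")


@dataclass(frozen=True)
class EffectConfig:
    """Cohort sizes, planted group effects and noise levels.

    Defaults encode the study conditions: 44 MCI vs. 42 HC participants,
    two language tasks, and group effects in the reported directions with
    magnitudes large enough to be clearly significant at this sample size
    (overlapping distributions, standardized differences around 1-1.5).
    """

    n_mci: int = 44
    n_hc: int = 42
    tasks: tuple[str, ...] = ("task1", "task2")
    seed: int = 0

    # --- EEG ---
    fs_eeg: float = 256.0
    eeg_rest_s: float = 30.0
    eeg_task_s: float = 30.0
    #: resting-state band powers, microvolt^2 (delta..gamma)
    band_powers_rest: tuple[float, ...] = (30.0, 15.0, 20.0, 8.0, 3.0)
    #: task-over-rest low-frequency (delta/theta) power factor, HC
    task_low_freq_boost_hc: float = 1.2
    #: extra MCI multiplier on task-state theta power (the clearest band)
    theta_power_boost_mci: float = 1.6
    #: extra MCI multiplier on task-state delta power (weaker than theta)
    delta_power_boost_mci: float = 1.25
    #: left-over-right hemispheric power ratio (nonzero DASM/RASM truth)
    left_right_power_ratio: float = 1.1
    #: lognormal sigma of per-subject band-power scatter
    subject_sigma: float = 0.25

    # --- speech ---
    fs_audio: float = 16000.0
    f0_mean_hz: float = 150.0
    f0_between_subject_sd_hz: float = 20.0
    jitter_fraction: float = 0.01
    formant_freqs_hz: tuple[float, ...] = (700.0, 1220.0, 2600.0)
    formant_bandwidths_hz: tuple[float, ...] = (80.0, 100.0, 120.0)
    speech_total_s_hc: float = 8.0
    effective_speech_ratio_mci: float = 0.65
    #: lognormal sigma of per-subject total-speech-time scatter
    speech_between_subject_sigma: float = 0.25
    burst_s_mean: float = 1.3
    burst_s_sd: float = 0.3
    short_pause_prob_hc: float = 0.7
    short_pause_ratio_delta: float = -0.3  # added to the MCI short-pause probability
    short_pause_s: tuple[float, float] = (0.45, 0.08)  # mean, sd
    long_pause_s: tuple[float, float] = (1.6, 0.25)
    noise_floor: float = 1e-4

    # --- transcript & digital parameters ---
    chars_per_second_hc: float = 3.5
    char_count_ratio_mci: float = 0.65
    #: lognormal sigma of per-recording character-rate scatter
    char_rate_sigma: float = 0.2
    test_time_s_hc: tuple[float, float] = (110.0, 25.0)  # mean, sd
    test_time_ratio_mci: float = 1.4


# ---------------------------------------------------------------------------
# EEG synthesis


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        low: float, high: float, power: float) -> np.ndarray:
    """Gaussian noise whose spectrum is confined to [low, high) Hz and whose
    variance equals ``power`` exactly (FFT masking + rescaling)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs >= high)] = 0.0
    x = np.fft.irfft(spec, n)
    std = x.std()
    if std == 0:
        return np.zeros(n)
    return x * (np.sqrt(power) / std)


def _synthesize_eeg(
    rng: np.random.Generator,
    cfg: EffectConfig,
    group: str,
    state: str,
    subject_factors: np.ndarray,
    duration_s: float,
) -> tuple[EEGRecording, dict]:
    """One 4-channel recording; returns the recording and its planted powers."""
    n = int(round(duration_s * cfg.fs_eeg))
    planted: dict[str, dict[str, float]] = {ch: {} for ch in EEG_CHANNELS}
    samples = np.zeros((len(EEG_CHANNELS), n))
    for ci, ch in enumerate(EEG_CHANNELS):
        side = cfg.left_right_power_ratio if ch in _LEFT_CHANNELS else 1.0
        for bi, band in enumerate(DEFAULT_BANDS):
            power = cfg.band_powers_rest[bi] * subject_factors[bi] * side
            if state == "task" and band.name in ("delta", "theta"):
                power *= cfg.task_low_freq_boost_hc
                if group == "MCI":
                    power *= (
                        cfg.theta_power_boost_mci
                        if band.name == "theta"
                        else cfg.delta_power_boost_mci
                    )
            samples[ci] += _band_limited_noise(
                rng, n, cfg.fs_eeg, band.low, band.high, power
            )
            planted[ch][band.name] = power
    rec = EEGRecording(samples=samples, fs=cfg.fs_eeg, state=state)
    return rec, planted


# ---------------------------------------------------------------------------
# Speech synthesis


def _vocal_tract_denominator(cfg: EffectConfig, fs: float) -> np.ndarray:
    a = np.array([1.0])
    for f, bw in zip(cfg.formant_freqs_hz, cfg.formant_bandwidths_hz):
        r = np.exp(-np.pi * bw / fs)
        section = np.array([1.0, -2.0 * r * np.cos(2.0 * np.pi * f / fs), r * r])
        a = np.convolve(a, section)
    return a


def _pulse_train(rng: np.random.Generator, n: int, fs: float,
                 f0: float, jitter_fraction: float) -> np.ndarray:
    """Impulse train with per-period jitter of the stated relative size."""
    x = np.zeros(n)
    t = 0.0
    base = 1.0 / f0
    while True:
        period = base * (1.0 + jitter_fraction * rng.standard_normal())
        t += max(period, 0.5 * base)
        idx = int(round(t * fs))
        if idx >= n:
            break
        x[idx] = 1.0
    return x


def _synthesize_speech(
    rng: np.random.Generator, cfg: EffectConfig, group: str, f0: float
) -> tuple[AudioRecording, dict]:
    """Bursty synthetic speech; returns audio and the ground-truth layout."""
    target_speech = cfg.speech_total_s_hc * (
        cfg.effective_speech_ratio_mci if group == "MCI" else 1.0
    )
    target_speech = float(
        np.clip(
            target_speech * np.exp(cfg.speech_between_subject_sigma
                                   * rng.standard_normal()),
            1.5,
            4.0 * cfg.speech_total_s_hc,
        )
    )
    p_short = cfg.short_pause_prob_hc + (
        cfg.short_pause_ratio_delta if group == "MCI" else 0.0
    )
    p_short = float(np.clip(p_short, 0.05, 0.95))

    bursts: list[float] = []
    total = 0.0
    while total < target_speech - 0.3:
        dur = float(np.clip(rng.normal(cfg.burst_s_mean, cfg.burst_s_sd), 0.6, 2.5))
        dur = min(dur, target_speech - total)
        if dur < 0.4:
            break
        bursts.append(dur)
        total += dur
    if not bursts:
        bursts = [target_speech]
        total = target_speech

    pauses: list[tuple[float, str]] = []
    for _ in range(len(bursts) - 1):
        if rng.random() < p_short:
            dur = float(np.clip(rng.normal(*cfg.short_pause_s), 0.25, 0.9))
            pauses.append((dur, "short"))
        else:
            dur = float(np.clip(rng.normal(*cfg.long_pause_s), 1.1, 2.4))
            pauses.append((dur, "long"))

    fs = cfg.fs_audio
    edge = 0.3
    segments: list[np.ndarray] = [np.zeros(int(edge * fs))]
    layout = {"speech": [], "pauses": [], "f0": f0, "total_speech_s": 0.0}
    a = _vocal_tract_denominator(cfg, fs)
    t_cursor = edge
    for i, dur in enumerate(bursts):
        n = int(round(dur * fs))
        pulses = _pulse_train(rng, n, fs, f0, cfg.jitter_fraction)
        voiced = sps.lfilter([1.0], a, pulses)
        peak = np.abs(voiced).max()
        if peak > 0:
            voiced = voiced * (0.6 / peak)
        segments.append(voiced)
        layout["speech"].append((round(t_cursor, 4), round(t_cursor + n / fs, 4)))
        t_cursor += n / fs
        if i < len(pauses):
            pdur, pcls = pauses[i]
            m = int(round(pdur * fs))
            segments.append(np.zeros(m))
            layout["pauses"].append((round(t_cursor, 4), round(t_cursor + m / fs, 4), pcls))
            t_cursor += m / fs
    segments.append(np.zeros(int(edge * fs)))
    x = np.concatenate(segments)
    x = x + cfg.noise_floor * rng.standard_normal(x.size)
    layout["total_speech_s"] = float(sum(e - s for s, e in layout["speech"]))
    return AudioRecording(samples=x, fs=fs), layout


def _make_transcript(rng: np.random.Generator, n_chars: int) -> str:
    chars = rng.integers(0, len(_CHAR_POOL), size=max(n_chars, 0))
    pieces = []
    for i, c in enumerate(chars):
        pieces.append(_CHAR_POOL[c])
        if (i + 1) % 12 == 0:
            pieces.append("，")  # punctuation: excluded from the count
    return "".join(pieces)


# ---------------------------------------------------------------------------
# Cohort assembly


def generate_cohort(cfg: EffectConfig, out_dir: str | Path) -> CohortManifest:
    """Write a complete synthetic cohort under ``out_dir`` and return its manifest.

    Per participant: one resting EEG, and per task one task EEG, one WAV,
    one transcript, one digital-parameter CSV, plus a ``truth.json``
    sidecar with everything that was planted.  Regenerating with the same
    config yields byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    participants: list[Participant] = []
    recordings: dict[tuple[str, str, str], Path] = {}
    groups = ["MCI"] * cfg.n_mci + ["HC"] * cfg.n_hc

    for idx, group in enumerate(groups):
        pid = f"p{idx + 1:03d}"
        rng = np.random.default_rng([cfg.seed, idx])
        pdir = out_dir / pid
        pdir.mkdir(exist_ok=True)
        truth: dict = {"group": group, "tasks": {}}

        moca = int(rng.integers(18, 27)) if group == "MCI" else int(rng.integers(27, 31))
        mmse = int(rng.integers(24, 27)) if group == "MCI" else int(rng.integers(26, 31))
        participants.append(
            Participant(
                id=pid,
                group=group,
                age=float(np.round(np.clip(rng.normal(68.0, 5.0), 65.0, 88.0), 1)),
                sex="F" if rng.random() < 0.5 else "M",
                education=float(np.round(np.clip(rng.normal(10.0, 1.6), 5.0, 16.0), 1)),
                moca=moca,
                mmse=mmse,
            )
        )

        # per-subject band-power scatter, shared across states/tasks
        subject_factors = np.exp(cfg.subject_sigma * rng.standard_normal(len(BAND_ORDER)))
        f0 = float(np.clip(rng.normal(cfg.f0_mean_hz, cfg.f0_between_subject_sd_hz),
                           90.0, 320.0))

        rest, rest_planted = _synthesize_eeg(
            rng, cfg, group, "resting", subject_factors, cfg.eeg_rest_s
        )
        rest_path = pdir / "eeg_rest.csv"
        write_eeg_csv(rest, rest_path)
        truth["eeg_rest_band_powers"] = rest_planted
        truth["subject_band_factors"] = dict(zip(BAND_ORDER, map(float, subject_factors)))

        for task in cfg.tasks:
            eeg, task_planted = _synthesize_eeg(
                rng, cfg, group, "task", subject_factors, cfg.eeg_task_s
            )
            audio, layout = _synthesize_speech(rng, cfg, group, f0)
            rate = cfg.chars_per_second_hc * (
                cfg.char_count_ratio_mci if group == "MCI" else 1.0
            )
            n_chars = int(round(rate * layout["total_speech_s"]
                                * float(np.exp(cfg.char_rate_sigma
                                               * rng.standard_normal()))))
            text = _make_transcript(rng, n_chars)
            mean_t, sd_t = cfg.test_time_s_hc
            total_time = rng.normal(
                mean_t * (cfg.test_time_ratio_mci if group == "MCI" else 1.0), sd_t
            )
            total_time = float(max(total_time, audio.duration + 20.0))
            digital = DigitalParams(
                total_test_time=round(total_time, 3),
                recording_duration=round(audio.duration, 3),
                task_id=task,
            )

            paths = {
                "eeg_task": pdir / f"{task}_eeg.csv",
                "eeg_rest": rest_path,
                "audio": pdir / f"{task}_audio.wav",
                "transcript": pdir / f"{task}_transcript.txt",
                "digital": pdir / f"{task}_digital.csv",
            }
            write_eeg_csv(eeg, paths["eeg_task"])
            write_audio(audio, paths["audio"])
            paths["transcript"].write_text(text, encoding="utf-8")
            write_digital(digital, paths["digital"])
            for modality, p in paths.items():
                recordings[(pid, task, modality)] = p.resolve()
            truth["tasks"][task] = {
                "eeg_task_band_powers": task_planted,
                "speech_layout": layout,
                "n_chars": n_chars,
                "total_test_time": digital.total_test_time,
            }

        (pdir / "truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8"
        )

    manifest = CohortManifest(
        participants=participants,
        tasks=list(cfg.tasks),
        recordings=recordings,
        incomplete=set(),
    )
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def load_truth(out_dir: str | Path, pid: str) -> dict:
    """Read the planted ground-truth sidecar for one participant."""
    return json.loads((Path(out_dir) / pid / "truth.json").read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Feature-table toys for the selection / classification harness


def generate_separable_toy(
    n: int,
    d_informative: int = 2,
    d_noise: int = 8,
    margin: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-class Gaussian feature table with a mean shift planted on the
    informative columns only.

    Class means differ by ``margin`` (in within-class SD units) on each
    informative column and by 0 on the noise columns.  Labels are "MCI"
    (first n/2 rows) and "HC".
    """
    if n % 2:
        raise ValueError("n must be even")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rng = np.random.default_rng(seed)
    d = d_informative + d_noise
    X = rng.standard_normal((n, d))
    X[: n // 2, :d_informative] += margin
    cols = [f"inf{i}" for i in range(d_informative)] + [
        f"noise{i}" for i in range(d_noise)
    ]
    ids = [f"s{i:03d}" for i in range(n)]
    y = pd.Series(["MCI"] * (n // 2) + ["HC"] * (n // 2), index=ids, name="group")
    return pd.DataFrame(X, columns=cols, index=ids), y


def generate_band_toy(
    n: int,
    informative_bands: tuple[str, ...] = ("theta",),
    n_per_band: int = 4,
    margin: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """EEG-style feature table with group separation planted in chosen bands.

    Columns follow the extractor naming (``MP.TP9.theta`` ...) with
    ``n_per_band`` features per band; only columns of ``informative_bands``
    carry a class mean shift of ``margin`` SD.
    """
    rng = np.random.default_rng(seed)
    if n % 2:
        raise ValueError("n must be even")
    cols, shift = [], []
    for band in BAND_ORDER:
        for j in range(n_per_band):
            ch = EEG_CHANNELS[j % len(EEG_CHANNELS)]
            cols.append(f"MP.{ch}{j // len(EEG_CHANNELS)}.{band}".replace(f"{ch}0", ch))
            shift.append(margin if band in informative_bands else 0.0)
    X = rng.standard_normal((n, len(cols)))
    X[: n // 2] += np.asarray(shift)[None, :]
    ids = [f"s{i:03d}" for i in range(n)]
    y = pd.Series(["MCI"] * (n // 2) + ["HC"] * (n // 2), index=ids, name="group")
    return pd.DataFrame(X, columns=cols, index=ids), y


def config_to_dict(cfg: EffectConfig) -> dict:
    return asdict(cfg)
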