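"""Cohort data model and file I/O.

The screening study records, per participant and per language task, a
4-channel wearable-EEG trace (Muse-style headband: TP9, AF7, AF8, TP10 at
256 Hz, exported as a Mind-Monitor-style CSV), a mono speech recording
(WAV), a plain-text transcript, and two digital cognitive timing parameters
(total test time and recording duration).  A cohort manifest ties these
files to participants and their group label (MCI vs. healthy control),
demographics and screening-scale scores.

The manifest is a single CSV with one row per participant x task; modality
columns hold file paths relative to the manifest's directory, which keeps
the cohort diffable and hand-editable.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "Participant",
    "EEGRecording",
    "AudioRecording",
    "Transcript",
    "DigitalParams",
    "CohortManifest",
    "CohortFormatError",
    "EEG_CHANNELS",
    "read_manifest",
    "write_manifest",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_audio",
    "write_audio",
    "read_transcript",
    "read_digital",
    "count_characters",
]

#: Canonical Muse electrode order: left ear, left/right forehead, right ear.
EEG_CHANNELS = ("TP9", "AF7", "AF8", "TP10")

#: Mind-Monitor-style raw column names, in canonical channel order.
EEG_CSV_COLUMNS = tuple(f"RAW_{ch}" for ch in EEG_CHANNELS)

GROUPS = ("MCI", "HC")

#: Modalities every (participant, task) cell must provide to be complete.
MODALITIES = ("eeg_task", "eeg_rest", "audio", "transcript", "digital")

MANIFEST_COLUMNS = (
    "participant_id",
    "group",
    "age",
    "sex",
    "education",
    "moca",
    "mmse",
    "task_id",
) + MODALITIES


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort file does not match its schema."""


@dataclass(frozen=True)
class Participant:
    """One study participant with group label and screening scores.

    The study's inclusion rule is MMSE >= 24 for everyone and MoCA <= 26
    for the MCI group (MoCA > 26 for controls); ``validate`` warns, rather
    than errors, when a record violates it, since real cohorts contain
    protocol deviations worth keeping visible.
    """

    id: str
    group: str  # "MCI" or "HC"
    age: float
    sex: str  # "F" or "M"
    education: float  # years
    moca: int
    mmse: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not (0 <= self.moca <= 30):
            raise ValueError(f"MoCA score {self.moca} outside [0, 30]")
        if not (0 <= self.mmse <= 30):
            raise ValueError(f"MMSE score {self.mmse} outside [0, 30]")

    def validate(self) -> list[str]:
        """Return inclusion-rule warnings (also emitted via ``warnings``)."""
        notes = []
        if self.mmse < 24:
            notes.append(f"{self.id}: MMSE {self.mmse} < 24 inclusion threshold")
        if self.group == "MCI" and self.moca > 26:
            notes.append(f"{self.id}: labelled MCI but MoCA {self.moca} > 26")
        if self.group == "HC" and self.moca <= 26:
            notes.append(f"{self.id}: labelled HC but MoCA {self.moca} <= 26")
        for n in notes:
            warnings.warn(n, stacklevel=2)
        return notes


@dataclass
class EEGRecording:
    """Four-channel EEG trace in canonical TP9, AF7, AF8, TP10 order.

    ``samples`` has shape (4, n); units are microvolts.  ``state``
    distinguishes the eyes-open resting baseline from the in-task trace.
    """

    samples: np.ndarray
    fs: float = 256.0
    channels: tuple[str, ...] = EEG_CHANNELS
    state: str = "task"  # "resting" or "task"
    task_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"samples must be ({len(self.channels)}, n), got {self.samples.shape}"
            )
        if tuple(self.channels) != EEG_CHANNELS:
            raise ValueError(f"channels must be exactly {EEG_CHANNELS}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.state not in ("resting", "task"):
            raise ValueError(f"state must be 'resting' or 'task', got {self.state!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channels.index(name)]
        except ValueError:
            raise ValueError(f"unknown channel {name!r}; have {self.channels}") from None


@dataclass
class AudioRecording:
    """Mono speech recording; samples are float in [-1, 1]."""

    samples: np.ndarray
    fs: float
    task_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class Transcript:
    """What the participant said during a task, as UTF-8 text.

    Only the character count enters the feature bank; the counting rule
    (non-whitespace, non-punctuation; CJK-safe) lives in
    :func:`count_characters`.
    """

    text: str
    task_id: str | None = None

    @property
    def counted_characters(self) -> int:
        return count_characters(self.text)


def count_characters(text: str) -> int:
    """Count transcript characters: everything except whitespace and punctuation.

    The cohort speaks Chinese, where the character (not the word) is the
    natural production unit, so counting is per code point with whitespace
    and punctuation (ASCII and CJK) excluded.
    """
    import unicodedata

    return sum(
        1
        for ch in text
        if not ch.isspace() and not unicodedata.category(ch).startswith("P")
    )


@dataclass
class DigitalParams:
    """VR-derived timing parameters for one participant x task, in seconds.

    ``None`` encodes a missing measurement; cleaning imputes it later.
    """

    total_test_time: float | None
    recording_duration: float | None
    task_id: str | None = None

    def __post_init__(self) -> None:
        for name in ("total_test_time", "recording_duration"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 or missing, got {v}")

    @property
    def missing(self) -> dict[str, bool]:
        return {
            "total_test_time": self.total_test_time is None,
            "recording_duration": self.recording_duration is None,
        }


@dataclass
class CohortManifest:
    """The cohort: participants, ordered task ids, and per-cell file paths.

    ``recordings`` maps (participant_id, task_id, modality) -> absolute
    Path. Cells missing one or more modalities are listed in ``incomplete``
    (flagged, never silently dropped) and are excluded from fusion.
    """

    participants: list[Participant]
    tasks: list[str]
    recordings: dict[tuple[str, str, str], Path]
    incomplete: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortFormatError(f"duplicate participant ids: {dupes}")

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def labels(self) -> dict[str, str]:
        return {p.id: p.group for p in self.participants}

    def complete_cells(self) -> list[tuple[str, str]]:
        return [
            (p.id, t)
            for p in self.participants
            for t in self.tasks
            if (p.id, t) not in self.incomplete
        ]

    def path(self, pid: str, task: str, modality: str) -> Path:
        return self.recordings[(pid, task, modality)]


# ---------------------------------------------------------------------------
# Manifest I/O


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Relative modality paths are resolved against the manifest's directory.
    A row with an empty modality cell flags that (participant, task) cell
    as incomplete.
    """
    path = Path(path)
    base = path.parent
    participants: dict[str, Participant] = {}
    tasks: list[str] = []
    recordings: dict[tuple[str, str, str], Path] = {}
    incomplete: set[tuple[str, str]] = set()

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing_cols:
            raise CohortFormatError(
                f"manifest {path} missing columns {missing_cols}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                p = Participant(
                    id=row["participant_id"],
                    group=row["group"],
                    age=float(row["age"]),
                    sex=row["sex"],
                    education=float(row["education"]),
                    moca=int(row["moca"]),
                    mmse=int(row["mmse"]),
                )
            except (KeyError, ValueError) as exc:
                raise CohortFormatError(f"manifest {path} row {i}: {exc}") from exc
            if p.id in participants and participants[p.id] != p:
                raise CohortFormatError(
                    f"manifest {path} row {i}: participant {p.id!r} re-declared "
                    "with different attributes"
                )
            participants.setdefault(p.id, p)
            task = row["task_id"]
            if task not in tasks:
                tasks.append(task)
            for modality in MODALITIES:
                cell = (row.get(modality) or "").strip()
                if not cell:
                    incomplete.add((p.id, task))
                else:
                    recordings[(p.id, task, modality)] = (base / cell).resolve()

    return CohortManifest(
        participants=list(participants.values()),
        tasks=tasks,
        recordings=recordings,
        incomplete=incomplete,
    )


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    """Write a manifest CSV; paths are stored relative to the CSV's directory."""
    path = Path(path)
    base = path.parent.resolve()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for p in manifest.participants:
            for task in manifest.tasks:
                cells = []
                for modality in MODALITIES:
                    fp = manifest.recordings.get((p.id, task, modality))
                    if fp is None:
                        cells.append("")
                    else:
                        fp = Path(fp).resolve()
                        try:
                            cells.append(str(fp.relative_to(base)))
                        except ValueError:
                            cells.append(str(fp))
                writer.writerow(
                    [p.id, p.group, p.age, p.sex, p.education, p.moca, p.mmse, task]
                    + cells
                )


# ---------------------------------------------------------------------------
# Signal readers / writers


def read_eeg_csv(
    path: str | Path,
    fs: float = 256.0,
    state: str = "task",
    task_id: str | None = None,
) -> EEGRecording:
    """Read a Mind-Monitor-style raw EEG CSV into canonical channel order.

    Requires the four RAW_* columns; tolerates extra columns (timestamps,
    band-power exports) and any column order.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty EEG CSV") from None
        header = [h.strip() for h in header]
        try:
            idx = [header.index(col) for col in EEG_CSV_COLUMNS]
        except ValueError:
            missing = [c for c in EEG_CSV_COLUMNS if c not in header]
            raise CohortFormatError(f"{path}: missing channel columns {missing}") from None
        rows = []
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                rows.append([float(row[j]) for j in idx])
            except (ValueError, IndexError):
                raise CohortFormatError(
                    f"{path}: non-numeric or short row at line {i}"
                ) from None
    if not rows:
        raise CohortFormatError(f"{path}: EEG CSV has no data rows")
    samples = np.asarray(rows, dtype=float).T
    return EEGRecording(samples=samples, fs=fs, state=state, task_id=task_id)


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the dialect :func:`read_eeg_csv` reads."""
    t = np.arange(rec.n_samples) / rec.fs
    table = np.column_stack([t, rec.samples.T])
    np.savetxt(
        path,
        table,
        delimiter=",",
        fmt=["%.6f"] + ["%.4f"] * len(rec.channels),
        header=",".join(("TimeStamp",) + EEG_CSV_COLUMNS),
        comments="",
    )


def read_audio(path: str | Path, task_id: str | None = None) -> AudioRecording:
    """Read a PCM WAV file; stereo is mixed down by averaging the channels."""
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except Exception as exc:
        raise CohortFormatError(f"{path}: unreadable WAV ({exc})") from exc
    if data.size == 0:
        raise CohortFormatError(f"{path}: empty WAV")
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(np.iinfo(data.dtype).max)
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    if data.ndim == 2:  # channel average, mic configuration unknown
        data = data.mean(axis=1)
    return AudioRecording(samples=data, fs=float(fs), task_id=task_id)


def write_audio(rec: AudioRecording, path: str | Path) -> None:
    """Write 16-bit PCM WAV, clipping to [-1, 1]."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    wavfile.write(path, int(rec.fs), (clipped * 32767.0).astype(np.int16))


def read_transcript(path: str | Path, task_id: str | None = None) -> Transcript:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except Exception as exc:
        raise CohortFormatError(f"{path}: unreadable transcript ({exc})") from exc
    return Transcript(text=text, task_id=task_id)


def read_digital(path: str | Path, task_id: str | None = None) -> DigitalParams:
    """Read a digital-parameter CSV (columns total_test_time, recording_duration).

    Empty cells become missing values (None) to be imputed by cleaning.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "total_test_time",
            "recording_duration",
        } <= set(reader.fieldnames):
            raise CohortFormatError(
                f"{path}: need columns total_test_time, recording_duration"
            )
        try:
            row = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: no data row") from None

    def parse(cell: str | None) -> float | None:
        cell = (cell or "").strip()
        if not cell:
            return None
        try:
            return float(cell)
        except ValueError:
            raise CohortFormatError(f"{path}: non-numeric cell {cell!r}") from None

    return DigitalParams(
        total_test_time=parse(row.get("total_test_time")),
        recording_duration=parse(row.get("recording_duration")),
        task_id=task_id,
    )


def write_digital(params: DigitalParams, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["total_test_time", "recording_duration"])
        writer.writerow(
            [
                "" if params.total_test_time is None else f"{params.total_test_time:.3f}",
                "" if params.recording_duration is None else f"{params.recording_duration:.3f}",
            ]
        )
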