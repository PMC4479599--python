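"""Calibrated WAV I/O and the tabular manifests/annotations of a playback experiment.

Audio is carried as pressure waveforms in pascals (``AudioClip``).  A scalar
calibration (pascals per digital full scale) converts between file samples and
pressure; the canonical on-disk dialect is 32-bit float mono WAV at 48 kHz,
but integer PCM depths are accepted on read.  Trial metadata (subject, session,
trial type, treatment) and call annotations (onsets/offsets, syllable bounds)
live in plain CSV tables; all times are seconds on half-open intervals
``[onset, offset)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

#: standard in-air reference pressure, Pa
P_REF = 20e-6

#: default sampling rate, samples/s
DEFAULT_RATE = 48000

TREATMENT_NAMES = ("A", "B", "C", "D", "E", "F")

MANIFEST_COLUMNS = ["subject", "session", "trial_type", "treatment", "wav_path", "calibration"]
ANNOTATION_COLUMNS = [
    "wav_path", "call_id", "call_type", "onset_s", "offset_s",
    "syllable_index", "syllable_type", "syl_onset_s", "syl_offset_s",
]


class ValidationError(ValueError):
    """Raised when a manifest or annotation table violates its invariants."""


@dataclasses.dataclass
class AudioClip:
    """A sampled pressure signal.

    Parameters
    ----------
    samples : array of float
        Instantaneous pressure in pascals.
    rate : int
        Sampling rate in samples per second.
    start_time : float
        Offset of the first sample within the parent recording, seconds.
    """

    samples: np.ndarray
    rate: int = DEFAULT_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip is mono: expected a 1-D sample array")
        if self.samples.size < 1:
            raise ValueError("AudioClip must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioClip samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_s

    def segment(self, onset_s: float, offset_s: float) -> "AudioClip":
        """Extract ``[onset_s, offset_s)`` (times within the parent recording)."""
        if offset_s <= onset_s:
            raise ValueError("segment requires offset_s > onset_s")
        i0 = int(round((onset_s - self.start_time) * self.rate))
        i1 = int(round((offset_s - self.start_time) * self.rate))
        i0 = max(i0, 0)
        i1 = min(i1, self.samples.size)
        if i1 <= i0:
            raise ValueError("segment lies outside the clip")
        return AudioClip(self.samples[i0:i1], self.rate, start_time=self.start_time + i0 / self.rate)


@dataclasses.dataclass
class Syllable:
    """One syllable within a call; bounds in seconds within the recording."""

    type: str  # "chirp" | "whistle"
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.type not in ("chirp", "whistle"):
            raise ValidationError(f"unknown syllable type {self.type!r}")
        if not self.offset_s > self.onset_s:
            raise ValidationError("syllable offset must exceed onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclasses.dataclass
class CallAnnotation:
    """Manually delimited call: whole-call bounds plus ordered syllable bounds.

    Invariants: ``offset_s > onset_s``; syllables are nested within the call
    bounds, non-overlapping and time-ordered; a chirp call carries at most one
    syllable entry.
    """

    call_id: str
    call_type: str  # "CLC" | "chirp"
    onset_s: float
    offset_s: float
    syllables: list[Syllable] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.call_type not in ("CLC", "chirp"):
            raise ValidationError(f"unknown call type {self.call_type!r}")
        if not self.offset_s > self.onset_s:
            raise ValidationError(f"call {self.call_id}: offset must exceed onset")
        if self.call_type == "chirp" and len(self.syllables) > 1:
            raise ValidationError(f"call {self.call_id}: chirp calls have at most one syllable")
        eps = 1e-9
        prev_end = self.onset_s - eps
        for s in self.syllables:
            if s.onset_s < self.onset_s - eps or s.offset_s > self.offset_s + eps:
                raise ValidationError(f"call {self.call_id}: syllable outside call bounds")
            if s.onset_s < prev_end - eps:
                raise ValidationError(f"call {self.call_id}: syllables overlap or are unordered")
            prev_end = s.offset_s

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def shifted(self, dt: float) -> "CallAnnotation":
        """Return a copy with all times translated by ``dt`` seconds."""
        return CallAnnotation(
            self.call_id, self.call_type, self.onset_s + dt, self.offset_s + dt,
            [Syllable(s.type, s.onset_s + dt, s.offset_s + dt) for s in self.syllables],
        )


@dataclasses.dataclass
class TrialRecord:
    """One trial of a playback session.

    ``treatment`` is None exactly when ``trial_type`` is ``"control"``.
    """

    subject: str
    session: int
    trial_type: str  # "control" | "treatment"
    treatment: Optional[str]
    wav_path: str
    calibration: float = 1.0  # Pa per digital full scale

    def __post_init__(self) -> None:
        if self.trial_type not in ("control", "treatment"):
            raise ValidationError(f"unknown trial type {self.trial_type!r}")
        if self.trial_type == "control" and self.treatment is not None:
            raise ValidationError("control trials must not name a treatment")
        if self.trial_type == "treatment":
            if self.treatment not in TREATMENT_NAMES:
                raise ValidationError(f"treatment must be one of {TREATMENT_NAMES}")
        if not self.calibration > 0:
            raise ValidationError("calibration must be positive")


# ---------------------------------------------------------------------------
# WAV files


def read_wav(path, calibration: float = 1.0) -> AudioClip:
    """Read a mono WAV file and scale samples to pascals.

    ``calibration`` is the pressure in Pa that corresponds to digital full
    scale (1.0 for float files, the type maximum for integer PCM).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        x = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    return AudioClip(x * calibration, rate)


def write_wav(clip: AudioClip, path, calibration: float = 1.0) -> None:
    """Write a clip as 32-bit float mono WAV (inverse scaling of :func:`read_wav`)."""
    if clip.samples.size == 0:
        raise ValueError("refusing to write a zero-length clip")
    wavfile.write(str(path), int(clip.rate), (clip.samples / calibration).astype(np.float32))


# ---------------------------------------------------------------------------
# Manifest / annotation tables


def load_manifest(path) -> list[TrialRecord]:
    """Load the trial manifest CSV, validating every row.

    Raises :class:`ValidationError` naming each offending row (1-based data
    row numbers) if any record violates the trial invariants.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "calibration"]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    records: list[TrialRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        treatment = getattr(row, "treatment", None)
        if pd.isna(treatment) or treatment in ("", "none", "None"):
            treatment = None
        calibration = float(getattr(row, "calibration", 1.0))
        try:
            records.append(TrialRecord(
                subject=str(row.subject), session=int(row.session),
                trial_type=str(row.trial_type), treatment=treatment,
                wav_path=str(row.wav_path), calibration=calibration,
            ))
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError("invalid manifest rows:\n" + "\n".join(errors))
    return records


def load_annotations(path) -> dict[str, list[CallAnnotation]]:
    """Load the call-annotation CSV, one syllable per row, grouped by wav_path.

    Rows sharing (wav_path, call_id) define one call; syllable columns may be
    empty for calls annotated without syllable bounds.  Invariant violations
    raise :class:`ValidationError` naming the call.
    """
    df = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValidationError(f"annotations missing columns: {missing}")
    out: dict[str, list[CallAnnotation]] = {}
    errors: list[str] = []
    for (wav, call_id), grp in df.groupby(["wav_path", "call_id"], sort=False):
        grp = grp.sort_values("syl_onset_s") if "syl_onset_s" in grp else grp
        first = grp.iloc[0]
        syllables = []
        if "syllable_index" in grp.columns:
            for _, r in grp.iterrows():
                if pd.isna(r.get("syllable_index")):
                    continue
                syllables.append(Syllable(str(r["syllable_type"]),
                                          float(r["syl_onset_s"]), float(r["syl_offset_s"])))
        try:
            ann = CallAnnotation(str(call_id), str(first["call_type"]),
                                 float(first["onset_s"]), float(first["offset_s"]), syllables)
        except ValidationError as exc:
            errors.append(str(exc))
            continue
        out.setdefault(str(wav), []).append(ann)
    if errors:
        raise ValidationError("invalid annotations:\n" + "\n".join(errors))
    for anns in out.values():
        anns.sort(key=lambda a: a.onset_s)
    return out


def write_manifest(records: list[TrialRecord], path) -> None:
    rows = [{
        "subject": r.subject, "session": r.session, "trial_type": r.trial_type,
        "treatment": r.treatment if r.treatment is not None else "none",
        "wav_path": r.wav_path, "calibration": r.calibration,
    } for r in records]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def write_annotations(table: dict[str, list[CallAnnotation]], path) -> None:
    rows = []
    for wav, anns in table.items():
        for a in anns:
            if a.syllables:
                for i, s in enumerate(a.syllables):
                    rows.append({"wav_path": wav, "call_id": a.call_id, "call_type": a.call_type,
                                 "onset_s": a.onset_s, "offset_s": a.offset_s,
                                 "syllable_index": i, "syllable_type": s.type,
                                 "syl_onset_s": s.onset_s, "syl_offset_s": s.offset_s})
            else:
                rows.append({"wav_path": wav, "call_id": a.call_id, "call_type": a.call_type,
                             "onset_s": a.onset_s, "offset_s": a.offset_s,
                             "syllable_index": None, "syllable_type": None,
                             "syl_onset_s": None, "syl_offset_s": None})
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)
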