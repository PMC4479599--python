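"""Synthetic vocalizations with known ground truth.

Two call types are emulated:

* the combination long call (CLC) — one short high-frequency chirp syllable
  followed by four tonal whistle syllables (fundamental ~1.5–1.7 kHz, up to
  eight harmonics, energy concentrated in the second harmonic) separated by
  ~0.1 s pauses;
* the short chirp — a single ~54 ms upsweep with a high fundamental and a
  weak second harmonic.

Syllables are additive harmonic stacks: ``Σ_k √w_k · sin(2π·k·φ(t))`` with
``φ`` the integral of a linear fundamental sweep, 5 ms raised-cosine on/off
ramps, scaled to an rms level in dB re 20 μPa.  ``harmonic_weights`` are
relative *power* weights, so the programmed spectral-density ratio between
harmonics of a steady tone equals the weight ratio directly.

A :class:`ResponseModel` holds generator-side effect sizes — Lombard slope,
bandwidth interaction, chirp duration slope, fundamental-frequency shifts and
spectral-tilt slope — that the measurement and statistics modules must
recover.  :func:`simulate_experiment` assembles full seeded experiments
(WAV + manifest + annotations + truth table); :func:`simulate_truth` produces
the parameter-level truth table alone, which is what the statistical
calibration suites consume.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import audio_io, stimuli
from .audio_io import AudioClip, CallAnnotation, Syllable, TrialRecord, P_REF
from .stimuli import NoiseTreatment, AMBIENT_DB

log = logging.getLogger(__name__)

#: effective noise bandwidth (Hz) of the default spectral analysis
#: (Hamming window, 1024 points at 48 kHz): 1.3628 × 48000/1024
ANALYSIS_ENBW_HZ = 1.3628 * 48000 / 1024

RAMP_S = 0.005


@dataclasses.dataclass
class SyllableSpec:
    """Parameters of one synthesized syllable.

    ``harmonic_weights[k-1]`` is the relative power of harmonic ``k``; the
    fundamental weight must be positive.  The fundamental sweeps linearly
    from ``f0_start_hz`` to ``f0_end_hz``.
    """

    type: str  # "chirp" | "whistle"
    duration_s: float
    f0_start_hz: float
    f0_end_hz: float
    harmonic_weights: list[float]
    level_db: float  # rms level, dB re 20 μPa

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("syllable duration must be positive")
        if not self.harmonic_weights or self.harmonic_weights[0] <= 0:
            raise ValueError("fundamental weight must be positive")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic weights must be non-negative")

    @property
    def f0_max_hz(self) -> float:
        return max(self.f0_start_hz, self.f0_end_hz)

    @property
    def f0_min_hz(self) -> float:
        return min(self.f0_start_hz, self.f0_end_hz)


@dataclasses.dataclass
class CallSpec:
    """A call as an ordered list of syllables with inter-syllable pauses."""

    call_type: str  # "CLC" | "chirp"
    syllables: list[SyllableSpec]
    pauses_s: list[float]

    def __post_init__(self) -> None:
        if len(self.pauses_s) != max(len(self.syllables) - 1, 0):
            raise ValueError("need exactly len(syllables) - 1 pauses")
        if self.call_type == "chirp" and len(self.syllables) != 1:
            raise ValueError("a chirp call is a single syllable")

    @property
    def duration_s(self) -> float:
        return sum(s.duration_s for s in self.syllables) + sum(self.pauses_s)

    def whistles(self) -> list[SyllableSpec]:
        return [s for s in self.syllables if s.type == "whistle"]


@dataclasses.dataclass
class ResponseModel:
    """Generator-side noise-response effect sizes.

    All slopes act on ``Δ = noise level − ambient`` (dB).  The minimum-f0
    shift is a flat offset whose sign depends on the noise bandwidth class
    (broadband: downward; narrowband: non-negative).  A zero model leaves
    calls untouched.
    """

    lombard_slope: float = 0.0            # dB call level per dB noise
    lombard_bw_interaction: float = 0.0   # extra slope under broadband noise
    duration_slope_ms_per_db: float = 0.0  # chirp calls only
    peak_f0_slope_hz_per_db: float = 0.0
    min_f0_shift_broad_hz: float = 0.0
    min_f0_shift_narrow_hz: float = 0.0
    tilt_slope_per_db: float = 0.0        # change in harmonic-k/fundamental ratio per dB

    @classmethod
    def zero(cls) -> "ResponseModel":
        return cls()


#: defaults mimicking a strong long-call noise response: a clear Lombard
#: effect slightly stronger under broadband noise, an upward peak-f0 shift,
#: bandwidth-dependent minimum-f0 shifts, and a tilt ratio rising from ~2.5
#: toward ~6 at the loudest treatments
CLC_RESPONSE = ResponseModel(
    lombard_slope=0.5, lombard_bw_interaction=0.1,
    peak_f0_slope_hz_per_db=8.0,
    min_f0_shift_broad_hz=-100.0, min_f0_shift_narrow_hz=50.0,
    tilt_slope_per_db=0.16,
)

#: chirp response: weaker Lombard effect, a duration increase (~5.5 ms over
#: the mean noise excess), upward peak/maximum frequency shifts, no tilt change
CHIRP_RESPONSE = ResponseModel(
    lombard_slope=0.25, duration_slope_ms_per_db=0.45,
    peak_f0_slope_hz_per_db=8.0,
)


# ---------------------------------------------------------------------------
# Baseline call specs

CLC_WHISTLE_WEIGHTS = [1.0, 2.5, 0.8, 0.4, 0.2, 0.1, 0.05, 0.02]
CHIRP_WEIGHTS = [1.0, 0.3]


def default_clc_spec(f0_hz: float = 1600.0, level_db: float = 76.0) -> CallSpec:
    """Baseline long call: one chirp syllable + four near-flat whistles.

    Whistle fundamentals sit on fixed per-syllable multipliers of ``f0_hz``
    (the first whistle is the lowest, the second the loudest), matching the
    stereotyped shape of the call; the chirp syllable is an 8→11 kHz upsweep.
    """
    chirp = SyllableSpec("chirp", 0.060, 8000.0, 11000.0, list(CHIRP_WEIGHTS), level_db - 2.0)
    # whistle fundamentals spaced >= ~80 Hz so neighbouring mainlobes do not
    # merge in the averaged spectrum; the second whistle is the loudest
    mults = (1.00, 1.05, 1.10, 1.16)
    durs = (0.42, 0.46, 0.44, 0.40)
    lvls = (0.0, 2.0, 0.0, -1.0)
    whistles = [
        SyllableSpec("whistle", d, f0_hz * m, f0_hz * m, list(CLC_WHISTLE_WEIGHTS), level_db + dl)
        for m, d, dl in zip(mults, durs, lvls)
    ]
    return CallSpec("CLC", [chirp] + whistles, [0.10, 0.11, 0.09, 0.10])


def default_chirp_spec(duration_s: float = 0.0537, level_db: float = 80.0) -> CallSpec:
    """Baseline short chirp: a single 8→11 kHz upsweep, ~54 ms."""
    syl = SyllableSpec("chirp", duration_s, 8000.0, 11000.0, list(CHIRP_WEIGHTS), level_db)
    return CallSpec("chirp", [syl], [])


# ---------------------------------------------------------------------------
# Rendering


def synth_syllable(spec: SyllableSpec, rate: int = audio_io.DEFAULT_RATE) -> AudioClip:
    """Render one syllable by additive harmonic synthesis.

    Harmonics that would alias (``k·max(f0) ≥ rate/2``) are dropped with a
    logged warning.  5 ms raised-cosine ramps shape the onset/offset and the
    result is scaled to ``spec.level_db`` rms.
    """
    n = int(round(spec.duration_s * rate))
    t = np.arange(n) / rate
    sweep = (spec.f0_end_hz - spec.f0_start_hz) / spec.duration_s
    phase = spec.f0_start_hz * t + 0.5 * sweep * t ** 2  # integrated linear sweep
    x = np.zeros(n)
    for k, w in enumerate(spec.harmonic_weights, start=1):
        if k * spec.f0_max_hz >= rate / 2:
            if w > 0:
                log.warning("dropping aliased harmonic %d (%.0f Hz at %d Hz rate)",
                            k, k * spec.f0_max_hz, rate)
            continue
        if w > 0:
            x += np.sqrt(w) * np.sin(2 * np.pi * k * phase)
    ramp = int(round(RAMP_S * rate))
    if 2 * ramp > n:
        ramp = n // 2
    if ramp > 0:
        env = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= env
        x[n - ramp:] *= env[::-1]
    rms = np.sqrt(np.mean(x ** 2))
    if rms == 0:
        raise ValueError("syllable rendered silent (all harmonics aliased?)")
    target = P_REF * 10.0 ** (spec.level_db / 20.0)
    return AudioClip(x * (target / rms), rate)


def synth_call(call_spec: CallSpec, rate: int = audio_io.DEFAULT_RATE,
               call_id: str = "call") -> tuple[AudioClip, CallAnnotation]:
    """Render a full call; the annotation bounds match the rendered samples."""
    pieces: list[np.ndarray] = []
    sylls: list[Syllable] = []
    pos = 0
    for i, s in enumerate(call_spec.syllables):
        clip = synth_syllable(s, rate)
        sylls.append(Syllable(s.type, pos / rate, (pos + clip.samples.size) / rate))
        pieces.append(clip.samples)
        pos += clip.samples.size
        if i < len(call_spec.pauses_s):
            gap = int(round(call_spec.pauses_s[i] * rate))
            pieces.append(np.zeros(gap))
            pos += gap
    samples = np.concatenate(pieces)
    ann = CallAnnotation(call_id, call_spec.call_type, 0.0, samples.size / rate, sylls)
    return AudioClip(samples, rate), ann


# ---------------------------------------------------------------------------
# Analytic truth


def call_level_db(spec: CallSpec) -> float:
    """Rms level over the whole call extent (pauses included), dB re 20 μPa."""
    ms, total = 0.0, 0.0
    for s in spec.syllables:
        p = P_REF * 10.0 ** (s.level_db / 20.0)
        ms += p * p * s.duration_s
        total += s.duration_s
    total += sum(spec.pauses_s)
    return 20.0 * np.log10(np.sqrt(ms / total) / P_REF)


def whistle_level_db(spec: CallSpec) -> Optional[float]:
    """Linear-mean level of the whistle syllables, dB re 20 μPa."""
    ws = spec.whistles()
    if not ws:
        return None
    pas = [P_REF * 10.0 ** (s.level_db / 20.0) for s in ws]
    return 20.0 * np.log10(np.mean(pas) / P_REF)


def expected_tilt_ratio(spec: CallSpec, k: Optional[int] = None,
                        enbw_hz: float = ANALYSIS_ENBW_HZ) -> Optional[float]:
    """Expected measured tilt ratio (harmonic-k/fundamental spectral density).

    For a steady tone this is the programmed power-weight ratio; for a swept
    fundamental each harmonic's energy spreads over ``k×`` the sweep extent,
    so the density ratio is the weight ratio divided by the relative
    spreading (sweep extents broadened by the analysis bandwidth).
    """
    if k is None:
        k = 3 if spec.call_type == "CLC" else 2
    cands = spec.whistles() if spec.call_type == "CLC" else spec.syllables
    cands = [s for s in cands if len(s.harmonic_weights) >= k]
    if not cands:
        return None
    s = max(cands, key=lambda q: q.level_db)
    sweep = abs(s.f0_end_hz - s.f0_start_hz)
    spread = (sweep + enbw_hz) / (k * sweep + enbw_hz)
    return (s.harmonic_weights[k - 1] / s.harmonic_weights[0]) * spread


def true_f0_min(spec: CallSpec) -> Optional[float]:
    segs = spec.whistles() if spec.call_type == "CLC" else spec.syllables
    if not segs:
        return None
    return min(s.f0_min_hz for s in segs)


def true_f0_peak(spec: CallSpec) -> Optional[float]:
    """Expected peak of the fundamental-only spectrum: the loudest whistle's
    fundamental for long calls; for a linear chirp sweep the density is
    near-uniform over the sweep, so the expected peak sits mid-sweep."""
    if spec.call_type == "CLC":
        ws = spec.whistles()
        if not ws:
            return None
        s = max(ws, key=lambda q: q.level_db)
        return (s.f0_start_hz + s.f0_end_hz) / 2
    s = spec.syllables[0]
    return (s.f0_start_hz + s.f0_end_hz) / 2


def true_peak_freq(spec: CallSpec) -> Optional[float]:
    """Expected whole-spectrum peak: the strongest harmonic of the loudest
    whistle for long calls (the second, at the default weights); mid-sweep
    of the fundamental for chirps."""
    if spec.call_type == "CLC":
        ws = spec.whistles()
        if not ws:
            return None
        s = max(ws, key=lambda q: q.level_db)
        k = 1 + int(np.argmax(s.harmonic_weights))
        return k * (s.f0_start_hz + s.f0_end_hz) / 2
    return true_f0_peak(spec)


def apply_response(base: CallSpec, noise_db_above_ambient: float, bandwidth_class: str,
                   model: ResponseModel) -> CallSpec:
    """Apply the noise-response model to a baseline call spec.

    ``Δ = noise_db_above_ambient`` must be non-negative; Δ = 0 returns an
    unchanged (deep) copy.  Level gains the Lombard slope (plus the broadband
    interaction), chirp durations grow by the duration slope, whistle
    fundamentals outside the call minimum shift by the peak-f0 slope, the
    minimum fundamental shifts by the bandwidth-dependent offset, and
    harmonic weights are rescaled so the tilt ratio of the measured harmonic
    grows by ``tilt_slope·Δ``.  Weights driven negative are clipped at zero
    with a warning.
    """
    if noise_db_above_ambient < 0:
        raise ValueError("noise_db_above_ambient must be non-negative")
    spec = copy.deepcopy(base)
    d = noise_db_above_ambient
    if d == 0:
        return spec
    if bandwidth_class not in ("broad", "narrow"):
        raise ValueError("bandwidth_class must be 'broad' or 'narrow'")

    slope = model.lombard_slope + (model.lombard_bw_interaction if bandwidth_class == "broad" else 0.0)
    for s in spec.syllables:
        s.level_db += slope * d

    if spec.call_type == "chirp":
        for s in spec.syllables:
            s.duration_s += model.duration_slope_ms_per_db * d / 1000.0
            s.f0_end_hz += model.peak_f0_slope_hz_per_db * d
    else:
        ws = spec.whistles()
        if ws:
            low = min(ws, key=lambda q: q.f0_min_hz)
            shift = (model.min_f0_shift_broad_hz if bandwidth_class == "broad"
                     else model.min_f0_shift_narrow_hz)
            for s in ws:
                if s is low:
                    s.f0_start_hz += shift
                    s.f0_end_hz += shift
                else:
                    s.f0_start_hz += model.peak_f0_slope_hz_per_db * d
                    s.f0_end_hz += model.peak_f0_slope_hz_per_db * d

    if model.tilt_slope_per_db != 0.0:
        k = 3 if spec.call_type == "CLC" else 2
        targets = spec.whistles() if spec.call_type == "CLC" else spec.syllables
        for s in targets:
            if len(s.harmonic_weights) < k or s.harmonic_weights[k - 1] <= 0:
                continue
            ratio = s.harmonic_weights[k - 1] / s.harmonic_weights[0]
            new_ratio = ratio + model.tilt_slope_per_db * d
            if new_ratio < 0:
                log.warning("tilt adjustment drove harmonic %d weight negative; clipping at 0", k)
                new_ratio = 0.0
            scale = new_ratio / ratio
            s.harmonic_weights = [s.harmonic_weights[0]] + [w * scale for w in s.harmonic_weights[1:]]
    return spec


# ---------------------------------------------------------------------------
# Experiment simulation


@dataclasses.dataclass
class SubjectSpec:
    name: str
    clc_base: Optional[CallSpec]
    chirp_base: Optional[CallSpec]
    clcs_per_trial: int = 4
    chirps_per_trial: int = 6


@dataclasses.dataclass
class SimConfig:
    """Configuration of a simulated playback experiment.

    Defaults follow the study layout this generator emulates: each subject
    receives six sessions of one control + one treatment trial (12 trials),
    treatments spanning 44–64 dB over two bandwidth classes above a 42 dB
    ambient floor.  ``trial_s`` defaults to 60 s — a desk-scale stand-in for
    the 12-minute trials, long enough to hold a full complement of calls and
    a 5 s call-free noise window.
    """

    subjects: list[SubjectSpec]
    treatments: list[NoiseTreatment] = dataclasses.field(default_factory=stimuli.treatment_bank)
    seed: int = 0
    ambient_db: float = AMBIENT_DB
    trial_s: float = 60.0
    rate: int = audio_io.DEFAULT_RATE
    clc_model: ResponseModel = dataclasses.field(default_factory=lambda: copy.deepcopy(CLC_RESPONSE))
    chirp_model: ResponseModel = dataclasses.field(default_factory=lambda: copy.deepcopy(CHIRP_RESPONSE))
    level_jitter_db: float = 1.5     # per-call lognormal level jitter (sd in dB)
    duration_jitter_cv: float = 0.05  # per-call normal fractional duration jitter
    f0_jitter_cv: float = 0.02        # per-call normal fractional f0 jitter
    tilt_jitter_cv: float = 0.15      # per-call lognormal jitter on harmonic/fundamental ratios
    subject_level_sd_db: float = 2.0  # between-subject baseline level spread
    subject_f0_sd: float = 0.03       # between-subject fractional f0 spread
    min_gap_s: float = 0.5
    preroll_s: float = 8.0            # call-free lead-in kept for noise estimation


def make_default_config(n_subjects: int = 3, seed: int = 0, **overrides) -> SimConfig:
    """Seeded default experiment: ``n_subjects`` producing both call types,
    with per-subject baseline level and f0 offsets."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(subjects=[], seed=seed, **overrides)
    for i in range(n_subjects):
        dl = rng.normal(0.0, cfg.subject_level_sd_db)
        df0 = 1.0 + rng.normal(0.0, cfg.subject_f0_sd)
        clc = default_clc_spec(f0_hz=1600.0 * df0, level_db=76.0 + dl)
        chirp = default_chirp_spec(level_db=80.0 + dl)
        cfg.subjects.append(SubjectSpec(f"S{i + 1}", clc, chirp))
    return cfg


def _jitter_call(spec: CallSpec, cfg: SimConfig, rng: np.random.Generator) -> CallSpec:
    spec = copy.deepcopy(spec)
    dl = rng.normal(0.0, cfg.level_jitter_db)
    fdur = max(1.0 + rng.normal(0.0, cfg.duration_jitter_cv), 0.5)
    ff0 = max(1.0 + rng.normal(0.0, cfg.f0_jitter_cv), 0.5)
    ftilt = float(np.exp(rng.normal(0.0, cfg.tilt_jitter_cv)))
    for s in spec.syllables:
        s.level_db += dl
        s.duration_s *= fdur
        s.f0_start_hz *= ff0
        s.f0_end_hz *= ff0
        if len(s.harmonic_weights) > 1:
            s.harmonic_weights = [s.harmonic_weights[0]] + [w * ftilt for w in s.harmonic_weights[1:]]
    spec.pauses_s = [p * fdur for p in spec.pauses_s]
    return spec


def _truth_row(spec: CallSpec, subject: str, session: int, trial_id: str, trial_type: str,
               treatment: Optional[str], bw: str, noise_db: float, call_id: str,
               onset_s: Optional[float]) -> dict:
    ws = spec.whistles()
    return {
        "subject": subject, "session": session, "trial_id": trial_id,
        "trial_type": trial_type, "treatment": treatment or "none",
        "bandwidth_class": bw, "noise_db": noise_db,
        "call_id": call_id, "call_type": spec.call_type, "onset_s": onset_s,
        "level_db": call_level_db(spec),
        "whistle_level_db": whistle_level_db(spec),
        "duration_s": spec.duration_s,
        "whistle_duration_s": float(np.mean([s.duration_s for s in ws])) if ws else None,
        "f0_min_hz": true_f0_min(spec),
        "f0_peak_hz": true_f0_peak(spec),
        "peak_freq_hz": true_peak_freq(spec),
        "whistle_peak_hz": (2.0 * float(np.mean([(s.f0_start_hz + s.f0_end_hz) / 2 for s in ws]))
                            if ws else None),
        "max_freq_hz": spec.syllables[0].f0_max_hz if spec.call_type == "chirp" else None,
        "min_freq_hz": spec.syllables[0].f0_min_hz if spec.call_type == "chirp" else None,
        "tilt_ratio": expected_tilt_ratio(spec),
    }


def _iter_trials(cfg: SimConfig, rng: np.random.Generator):
    """Yield (subject, session, trial_type, treatment|None, bw_class, noise_db)
    in a deterministic order; treatment order and within-session trial order
    are randomized per subject."""
    for subj in cfg.subjects:
        order = rng.permutation(len(cfg.treatments))
        for session, ti in enumerate(order, start=1):
            tr = cfg.treatments[int(ti)]
            kinds = ["control", "treatment"]
            if rng.random() < 0.5:
                kinds.reverse()
            for kind in kinds:
                if kind == "control":
                    yield subj, session, "control", None, tr.bandwidth_class, cfg.ambient_db
                else:
                    yield subj, session, "treatment", tr, tr.bandwidth_class, tr.target_db


def _trial_calls(cfg: SimConfig, subj: SubjectSpec, treatment: Optional[NoiseTreatment],
                 bw: str, rng: np.random.Generator) -> list[CallSpec]:
    d = max(treatment.target_db - cfg.ambient_db, 0.0) if treatment is not None else 0.0
    specs: list[CallSpec] = []
    if subj.clc_base is not None:
        for _ in range(subj.clcs_per_trial):
            s = apply_response(subj.clc_base, d, bw, cfg.clc_model) if d > 0 else copy.deepcopy(subj.clc_base)
            specs.append(_jitter_call(s, cfg, rng))
    if subj.chirp_base is not None:
        for _ in range(subj.chirps_per_trial):
            s = apply_response(subj.chirp_base, d, bw, cfg.chirp_model) if d > 0 else copy.deepcopy(subj.chirp_base)
            specs.append(_jitter_call(s, cfg, rng))
    return specs


def simulate_truth(cfg: SimConfig) -> pd.DataFrame:
    """Parameter-level simulation: the per-call truth table, no audio.

    Identical seeds give identical tables.  This is the fast path used for
    statistical calibration; :func:`simulate_experiment` renders the same
    structure to audio.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for subj, session, kind, tr, bw, noise_db in _iter_trials(cfg, rng):
        trial_id = f"{subj.name}_s{session:02d}_{kind}"
        for i, spec in enumerate(_trial_calls(cfg, subj, tr, bw, rng)):
            rows.append(_truth_row(spec, subj.name, session, trial_id, kind,
                                   tr.name if tr else None, bw, noise_db,
                                   f"{trial_id}_c{i:02d}", None))
    return pd.DataFrame(rows)


def simulate_experiment(cfg: SimConfig, out_dir) -> dict[str, object]:
    """Render a full experiment to ``out_dir``.

    Writes one WAV per trial (noise bed plus calls at randomized
    non-overlapping times, all after an 8 s call-free lead-in), a trial
    manifest CSV, a call-annotation CSV and the generator truth CSV.  The
    same seed yields byte-identical outputs.  Raises when the configured call
    density cannot be placed without overlap.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: list[TrialRecord] = []
    annotations: dict[str, list[CallAnnotation]] = {}
    truth_rows = []

    for subj, session, kind, tr, bw, noise_db in _iter_trials(cfg, rng):
        trial_id = f"{subj.name}_s{session:02d}_{kind}"
        wav_name = trial_id + ".wav"
        specs = _trial_calls(cfg, subj, tr, bw, rng)

        if tr is not None:
            bed = stimuli.band_limited_noise(tr, cfg.trial_s, cfg.rate, seed=rng)
        else:
            amb = AudioClip(rng.standard_normal(int(cfg.trial_s * cfg.rate)), cfg.rate)
            bed = stimuli.set_level_db(amb, cfg.ambient_db)
        samples = bed.samples.copy()

        total_call = sum(s.duration_s for s in specs)
        slack = cfg.trial_s - cfg.preroll_s - 1.0 - total_call - cfg.min_gap_s * len(specs)
        if slack < 0:
            raise ValueError(f"{trial_id}: call density too high to place without overlap")
        order = rng.permutation(len(specs))
        extra = rng.random(len(specs))
        extra = extra / max(extra.sum(), 1e-9) * slack * rng.random()
        t = cfg.preroll_s
        anns: list[CallAnnotation] = []
        for j, oi in enumerate(order):
            spec = specs[int(oi)]
            t += cfg.min_gap_s + float(extra[j])
            clip, ann = synth_call(spec, cfg.rate, call_id=f"{trial_id}_c{int(oi):02d}")
            i0 = int(round(t * cfg.rate))
            samples[i0:i0 + clip.samples.size] += clip.samples
            anns.append(ann.shifted(i0 / cfg.rate))
            truth_rows.append(_truth_row(spec, subj.name, session, trial_id, kind,
                                         tr.name if tr else None, bw, noise_db,
                                         ann.call_id, i0 / cfg.rate))
            t += clip.duration_s

        audio_io.write_wav(AudioClip(samples, cfg.rate), out / wav_name)
        manifest.append(TrialRecord(subj.name, session, kind, tr.name if tr else None,
                                    wav_name, 1.0))
        annotations[wav_name] = sorted(anns, key=lambda a: a.onset_s)

    truth = pd.DataFrame(truth_rows)
    audio_io.write_manifest(manifest, out / "manifest.csv")
    audio_io.write_annotations(annotations, out / "annotations.csv")
    truth.to_csv(out / "truth.csv", index=False)
    return {"dir": out, "manifest": manifest, "annotations": annotations, "truth": truth}
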