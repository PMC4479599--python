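"""Band-limited white-noise playback stimuli.

The treatment bank crosses two bandwidth classes — narrowband (1.5–6.5 kHz,
targeting the perceptually important low harmonics of long calls) and
broadband (0.1–10 kHz) — with three in-cage levels spanning 44–64 dB re
20 μPa rms, i.e. 2–22 dB above a ~42 dB ambient floor.  Treatments are named
A–C (narrowband high/medium/low) and D–F (broadband high/medium/low).

Stimuli are ideal band-limited Gaussian noise: white noise passed through a
zero-phase Butterworth band-pass whose corners are pre-warped so the measured
−3 dB edges of the forward-backward (squared-magnitude) response land on the
nominal band edges, then scaled to the target rms level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .audio_io import AudioClip, P_REF, DEFAULT_RATE

#: default filter order (per pass; the filter is applied forward and backward)
FILTER_ORDER = 8

#: default level grid, dB re 20 μPa rms, for (high, medium, low) amplitudes
DEFAULT_LEVELS = (64.0, 54.0, 44.0)

#: assumed ambient level during control trials, dB re 20 μPa rms
AMBIENT_DB = 42.0

NARROW_BAND = (1500.0, 6500.0)
BROAD_BAND = (100.0, 10000.0)


@dataclasses.dataclass(frozen=True)
class NoiseTreatment:
    """One playback stimulus: band edges plus target in-cage level."""

    name: str
    low_hz: float
    high_hz: float
    target_db: float  # dB re 20 μPa rms

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("band edges must satisfy 0 < low < high")

    @property
    def bandwidth_hz(self) -> float:
        return self.high_hz - self.low_hz

    @property
    def bandwidth_class(self) -> str:
        return "broad" if self.bandwidth_hz > 6000.0 else "narrow"


def treatment_bank(levels: tuple[float, float, float] = DEFAULT_LEVELS) -> list[NoiseTreatment]:
    """The six-treatment bank: {narrow, broad} × {high, medium, low} levels.

    A–C are narrowband (5 kHz bandwidth), D–F broadband (9.9 kHz bandwidth);
    within each class the levels run high → low.
    """
    bank = []
    for names, (lo, hi) in (("ABC", NARROW_BAND), ("DEF", BROAD_BAND)):
        for name, level in zip(names, levels):
            bank.append(NoiseTreatment(name, lo, hi, float(level)))
    return bank


def get_treatment(name: str, levels: tuple[float, float, float] = DEFAULT_LEVELS) -> NoiseTreatment:
    for t in treatment_bank(levels):
        if t.name == name:
            return t
    raise KeyError(f"no treatment named {name!r}")


def set_level_db(clip: AudioClip, target_db: float) -> AudioClip:
    """Rescale a clip so its rms equals ``20 μPa · 10^(target_db/20)``."""
    rms = float(np.sqrt(np.mean(clip.samples ** 2)))
    if rms == 0.0:
        raise ValueError("cannot set the level of an all-zero clip")
    target_pa = P_REF * 10.0 ** (target_db / 20.0)
    return AudioClip(clip.samples * (target_pa / rms), clip.rate, clip.start_time)


def _bandpass_sos(low_hz: float, high_hz: float, rate: int, order: int = FILTER_ORDER):
    """Butterworth band-pass with corners pre-warped for forward-backward use.

    filtfilt squares the magnitude response, moving the −3 dB (power) points
    inside the design corners by the factor ``(√2 − 1)^(1/2n)``; the corners
    are widened by that factor so the measured edges sit on the nominal ones.
    """
    warp = (np.sqrt(2.0) - 1.0) ** (1.0 / (2 * order))
    lo = low_hz * warp
    hi = min(high_hz / warp, rate / 2 * 0.999)
    return signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")


def band_limited_noise(treatment: NoiseTreatment, duration_s: float, rate: int = DEFAULT_RATE,
                       seed: int | np.random.Generator = 0) -> AudioClip:
    """Generate one stimulus: band-passed white noise at the treatment level.

    Reproducible for a fixed seed; out-of-band power sits ≥ 40 dB below the
    in-band mean PSD and the rms level matches ``treatment.target_db``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if treatment.high_hz >= rate / 2:
        raise ValueError("upper band edge must lie below the Nyquist frequency")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    white = rng.standard_normal(n)
    sos = _bandpass_sos(treatment.low_hz, treatment.high_hz, rate)
    shaped = signal.sosfiltfilt(sos, white)
    return set_level_db(AudioClip(shaped, rate), treatment.target_db)


def write_bank_csv(bank: list[NoiseTreatment], path) -> None:
    import pandas as pd

    pd.DataFrame([dataclasses.asdict(t) for t in bank],
                 columns=["name", "low_hz", "high_hz", "target_db"]).to_csv(path, index=False)
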