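"""Acoustic measurement of annotated calls.

Implements the measurement chain of a noise-playback experiment:

* sound-pressure levels with noise-energy subtraction — a call's received
  level is ``sqrt(mean_square(call clip) − mean_square(noise))``, the noise
  mean square coming from a 5 s vocalization-free window of the same trial;
* trial source levels as the linear-pascal mean of per-call rms values,
  converted to dB re 20 μPa afterwards;
* Welch-averaged power spectral densities (1024-point Hamming window, 75 %
  overlap, 4096-point DFT → 11.72 Hz bins at 48 kHz) with per-bin noise
  spectrum subtraction;
* harmonic peak finding and spectral tilt — the ratio of a higher harmonic's
  spectral density to the fundamental's (third harmonic for long calls,
  second for chirps);
* spectral extrema (minimum / peak / maximum frequency) as −24 dB-re-peak
  edge crossings on a median-smoothed spectrum, a reproducible stand-in for
  a manual "inflection point" reading;
* fundamental-frequency contours tracked as per-frame spectral argmax within
  a band around the fundamental, with min/peak f0 measured on the PSD of the
  fundamental-isolated (band-passed) signal;
* durations: whole-call duration includes inter-syllable pauses, which are
  excluded from per-syllable durations.

Levels are "source levels" in the loose sense of received level at a fixed
calibrated microphone; no distance back-propagation is applied.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .audio_io import AudioClip, CallAnnotation, P_REF

# Spectral-analysis defaults (Hamming window, 75% overlap, 4x zero-padding:
# 48000 / 4096 = 11.72 Hz bins)
WINDOW_LEN = 1024
OVERLAP = 0.75
DFT_LEN = 4096
EDGE_DB = 24.0
F0_BANDS = {"CLC": (800.0, 2600.0), "chirp": (5000.0, 16000.0)}
TILT_HARMONIC = {"CLC": 3, "chirp": 2}
K_MAX = {"CLC": 8, "chirp": 2}


class MeasurementError(ValueError):
    """Raised when a measurement's preconditions are not met."""


@dataclasses.dataclass
class Psd:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray  # Hz
    power: np.ndarray  # Pa^2 / Hz
    window_len: int
    overlap: float
    dft_len: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs/power must be matching 1-D arrays")
        d = np.diff(self.freqs)
        if not (np.all(d > 0) and np.allclose(d, d[0])):
            raise ValueError("frequency grid must be strictly increasing and uniform")
        if np.any(self.power < 0):
            raise ValueError("spectral density must be non-negative")

    @property
    def bin_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclasses.dataclass
class HarmonicPeak:
    k: int
    freq_hz: float
    density: float  # Pa^2 / Hz


@dataclasses.dataclass
class NoiseStats:
    """Trial background-noise summary used for level and spectrum subtraction."""

    mean_square: float  # Pa^2
    psd: Optional[Psd] = None

    @classmethod
    def silent(cls) -> "NoiseStats":
        return cls(0.0, None)


@dataclasses.dataclass
class F0Measures:
    f0_min_hz: Optional[float]
    f0_peak_hz: Optional[float]
    contour_times_s: np.ndarray
    contour_hz: np.ndarray


@dataclasses.dataclass
class CallMeasurements:
    """Fully populated per-call measurement record."""

    call_id: str
    call_type: str
    source_level_db: float
    level_reliable: bool
    duration_s: float
    syllable_durations_s: list[float]
    min_freq_hz: Optional[float]
    peak_freq_hz: Optional[float]
    max_freq_hz: Optional[float]
    f0_min_hz: Optional[float]
    f0_peak_hz: Optional[float]
    tilt_ratio: Optional[float]
    tilt_harmonic: int
    whistle_level_db: Optional[float] = None
    whistle_peak_hz: Optional[float] = None
    whistle_durations_s: Optional[list[float]] = None
    flags: list[str] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Levels


def rms(clip: AudioClip) -> float:
    """Root-mean-square pressure of a clip, Pa."""
    if clip.samples.size == 0:
        raise MeasurementError("empty clip")
    return float(np.sqrt(np.mean(clip.samples ** 2)))


def to_db_spl(p: float) -> float:
    """Convert a pressure in Pa to dB re 20 μPa."""
    if not p > 0:
        raise MeasurementError("pressure must be positive (noise over-subtraction upstream?)")
    return 20.0 * np.log10(p / P_REF)


def trial_noise_level(trial_clip: AudioClip, annotations: list[CallAnnotation],
                      window_s: float = 5.0, hop_s: float = 1.0) -> tuple[float, NoiseStats]:
    """Background level of a trial from the first ``window_s`` call-free window.

    Scans windows at ``hop_s`` steps from the start of the recording and
    returns ``(level_db, NoiseStats)`` for the first one that overlaps no
    annotated call.  Raises if the trial is shorter than the window or no
    call-free window exists.
    """
    total = trial_clip.duration_s
    if total < window_s:
        raise MeasurementError(f"trial shorter than the {window_s} s noise window")
    t0 = trial_clip.start_time
    intervals = [(a.onset_s, a.offset_s) for a in annotations]
    t = t0
    while t + window_s <= t0 + total + 1e-9:
        if not any(on < t + window_s and off > t for on, off in intervals):
            seg = trial_clip.segment(t, t + window_s)
            ms = float(np.mean(seg.samples ** 2))
            psd = averaged_psd(seg)
            return to_db_spl(np.sqrt(ms)), NoiseStats(ms, psd)
        t += hop_s
    raise MeasurementError("no vocalization-free noise window found")


def noise_subtracted_rms(call_clip: AudioClip, noise_ms: float) -> tuple[float, bool]:
    """Noise-energy-subtracted rms of a call clip.

    Returns ``(pressure_pa, reliable)`` where the pressure is
    ``sqrt(max(mean(call^2) − noise_ms, floor))``.  The result is flagged
    unreliable when the call's mean square is below twice the noise mean
    square (SNR < ~3 dB); over-subtraction is clamped at a small floor rather
    than raising.
    """
    if noise_ms < 0:
        raise MeasurementError("noise mean square must be non-negative")
    call_ms = float(np.mean(call_clip.samples ** 2))
    floor = max(1e-12 * call_ms, (P_REF * 1e-3) ** 2)
    reliable = call_ms >= 2.0 * noise_ms
    return float(np.sqrt(max(call_ms - noise_ms, floor))), reliable


def trial_source_level(call_levels_pa: list[float]) -> float:
    """Trial source level: mean of per-call rms pressures (linear pascals),
    then converted to dB re 20 μPa — in that order."""
    if len(call_levels_pa) == 0:
        raise MeasurementError("trial has no calls")
    return to_db_spl(float(np.mean(call_levels_pa)))


# ---------------------------------------------------------------------------
# Spectra


def averaged_psd(clip: AudioClip, window_len: int = WINDOW_LEN, overlap: float = OVERLAP,
                 dft_len: int = DFT_LEN) -> Psd:
    """Welch-averaged one-sided PSD with Hamming windowing and zero-padding.

    At the defaults and 48 kHz this gives 11.72 Hz bins.  A clip shorter than
    one window is analyzed as a single zero-padded segment (with a warning).
    """
    x = clip.samples
    if x.size < window_len:
        warnings.warn("clip shorter than the analysis window; using a single zero-padded segment")
        window_len = x.size
    freqs, power = signal.welch(
        x, fs=clip.rate, window="hamming", nperseg=window_len,
        noverlap=int(window_len * overlap), nfft=max(dft_len, window_len), detrend=False,
    )
    return Psd(freqs, power, window_len, overlap, dft_len)


def subtract_psd(call_psd: Psd, noise_psd: Psd) -> Psd:
    """Per-bin noise-spectrum subtraction, clamped at a floor of 1e-12 × peak."""
    if call_psd.freqs.shape != noise_psd.freqs.shape or not np.allclose(call_psd.freqs, noise_psd.freqs):
        raise MeasurementError("call and noise PSDs must share a frequency grid")
    floor = 1e-12 * float(np.max(call_psd.power))
    power = np.maximum(call_psd.power - noise_psd.power, floor)
    return Psd(call_psd.freqs, power, call_psd.window_len, call_psd.overlap, call_psd.dft_len)


def harmonic_peaks(psd: Psd, f0_est: float, k_max: int, tol: float = 0.15) -> list[HarmonicPeak]:
    """Find spectral peaks at (approximate) harmonics of ``f0_est``.

    For each harmonic order ``k ≤ k_max`` the maximum density within
    ``k·f0_est·(1 ± tol)`` is taken.  The fundamental must rise at least
    6 dB above the spectrum-wide median floor (else an error); higher
    harmonics whose band maximum falls below −40 dB re the fundamental's
    density (window-leakage territory) are omitted as absent.
    """
    if not psd.freqs[0] <= f0_est <= psd.freqs[-1]:
        raise MeasurementError("f0 estimate outside the PSD frequency range")
    floor = float(np.median(psd.power))
    peaks: list[HarmonicPeak] = []
    for k in range(1, k_max + 1):
        lo, hi = k * f0_est * (1 - tol), k * f0_est * (1 + tol)
        sel = np.flatnonzero((psd.freqs >= lo) & (psd.freqs <= hi))
        if sel.size < 3:
            continue
        band = psd.power[sel]
        i = int(np.argmax(band))
        if k == 1:
            if band[i] < 4.0 * floor:
                break
        elif band[i] < 1e-4 * peaks[0].density:
            continue
        peaks.append(HarmonicPeak(k, float(psd.freqs[sel[i]]), float(band[i])))
    if not peaks or peaks[0].k != 1:
        raise MeasurementError("no fundamental peak found")
    return peaks


def tilt_ratio(peaks: list[HarmonicPeak], k: int) -> Optional[float]:
    """Spectral-tilt ratio: density of harmonic ``k`` over the fundamental's.

    Returns None when harmonic ``k`` was not detected (the caller records the
    reason); a missing fundamental is a hard error.
    """
    by_k = {p.k: p for p in peaks}
    if 1 not in by_k:
        raise MeasurementError("fundamental missing from harmonic peaks")
    if k not in by_k:
        return None
    return by_k[k].density / by_k[1].density


def spectrum_extrema(psd: Psd, edge_db: float = EDGE_DB,
                     smooth_bins: int = 5) -> tuple[float, float, float]:
    """(min, peak, max) frequency of a spectrum.

    Peak is the argmax of the median-smoothed density; min and max are the
    outermost frequencies where the smoothed density still reaches
    ``peak − edge_db``.
    """
    p = ndimage.median_filter(psd.power, size=smooth_bins, mode="nearest")
    pmax = float(np.max(p))
    if pmax <= 0 or np.allclose(p, p[0]):
        raise MeasurementError("flat or empty spectrum")
    ipk = int(np.argmax(p))
    thresh = pmax * 10.0 ** (-edge_db / 10.0)
    above = np.flatnonzero(p >= thresh)
    fmin, fmax = float(psd.freqs[above[0]]), float(psd.freqs[above[-1]])
    return fmin, float(psd.freqs[ipk]), fmax


# ---------------------------------------------------------------------------
# Fundamental frequency


def _track_contour(clip: AudioClip, band: tuple[float, float], frame_len: int = 512,
                   hop: int = 128, nfft: int = DFT_LEN) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame argmax contour within ``band``; quiet frames are dropped."""
    x = clip.samples
    frame_len = min(frame_len, x.size)
    freqs, times, spec = signal.stft(
        x, fs=clip.rate, window="hamming", nperseg=frame_len,
        noverlap=frame_len - min(hop, frame_len - 1), nfft=max(nfft, frame_len),
        boundary=None, padded=False,
    )
    power = np.abs(spec) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        return np.array([]), np.array([])
    sub = power[sel, :]
    fgrid = freqs[sel]
    frame_energy = sub.sum(axis=0)
    if frame_energy.size == 0 or frame_energy.max() <= 0:
        return np.array([]), np.array([])
    keep = frame_energy >= 0.05 * frame_energy.max()
    contour = fgrid[np.argmax(sub[:, keep], axis=0)]
    return times[keep] + clip.start_time, contour


def f0_measures(clip: AudioClip, annotation: CallAnnotation,
                search_band: Optional[tuple[float, float]] = None,
                edge_db: float = EDGE_DB) -> F0Measures:
    """Fundamental-frequency measurements of a call.

    The contour is tracked as the per-frame spectral argmax within a band
    around the fundamental (for long calls, over the whistle syllables; for
    chirps, over the whole call).  The fundamental is then isolated with a
    zero-phase band-pass around the contour's range, and min/peak f0 are read
    from the PSD of the isolated signal: peak = argmax, min = the lower
    −``edge_db`` edge.  Returns missing values when no contour is found.
    """
    if search_band is None:
        search_band = F0_BANDS[annotation.call_type]
    if annotation.call_type == "CLC":
        segs = [s for s in annotation.syllables if s.type == "whistle"]
        if not segs:
            segs = annotation.syllables
        clips = [clip.segment(s.onset_s, s.offset_s) for s in segs]
    else:
        clips = [clip.segment(annotation.onset_s, annotation.offset_s)]

    times_all, contour_all = [], []
    for c in clips:
        t, f = _track_contour(c, search_band)
        times_all.append(t)
        contour_all.append(f)
    times = np.concatenate(times_all) if times_all else np.array([])
    contour = np.concatenate(contour_all) if contour_all else np.array([])
    if contour.size == 0:
        return F0Measures(None, None, times, contour)

    lo = max(float(contour.min()) * 0.85, 1.0)
    hi = min(float(contour.max()) * 1.15, clip.rate / 2 * 0.99)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=clip.rate, output="sos")

    # PSD of the fundamental-isolated signal; long syllables afford a full
    # 4096-point window (11.7 Hz resolution without zero-padding), which keeps
    # the -edge_db skirt of a steady tone within a couple of bins of its true
    # frequency.
    filtered = [signal.sosfiltfilt(sos, c.samples) for c in clips]
    x = np.concatenate(filtered)
    win = DFT_LEN if x.size >= DFT_LEN else WINDOW_LEN
    psd = averaged_psd(AudioClip(x, clip.rate), window_len=min(win, x.size))
    band_sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    sub = Psd(psd.freqs[band_sel], psd.power[band_sel], psd.window_len, psd.overlap, psd.dft_len)
    try:
        fmin, fpk, _ = spectrum_extrema(sub, edge_db=edge_db, smooth_bins=3)
    except MeasurementError:
        return F0Measures(None, None, times, contour)
    return F0Measures(fmin, fpk, times, contour)


# ---------------------------------------------------------------------------
# Durations and composition


def durations(annotation: CallAnnotation) -> tuple[float, list[float]]:
    """Whole-call duration (pauses included) and per-syllable durations
    (pauses excluded)."""
    return annotation.duration_s, [s.duration_s for s in annotation.syllables]


def measure_call(trial_clip: AudioClip, annotation: CallAnnotation, noise_stats: NoiseStats,
                 edge_db: float = EDGE_DB) -> CallMeasurements:
    """Measure one annotated call end to end.

    Long calls are measured on the whole call and per syllable; chirp
    frequency measurements use the fundamental contour only.  Questionable
    values are flagged, never silently NaN.
    """
    flags: list[str] = []
    call_clip = trial_clip.segment(annotation.onset_s, annotation.offset_s)
    p, reliable = noise_subtracted_rms(call_clip, noise_stats.mean_square)
    if not reliable:
        flags.append("level_unreliable")
    level_db = to_db_spl(p)
    whole_s, syl_s = durations(annotation)

    call_psd = averaged_psd(call_clip)
    if noise_stats.psd is not None:
        call_psd = subtract_psd(call_psd, noise_stats.psd)

    f0 = f0_measures(trial_clip, annotation, edge_db=edge_db)
    if f0.f0_peak_hz is None:
        flags.append("no_f0_contour")

    k_tilt = TILT_HARMONIC[annotation.call_type]
    tilt = None
    min_hz = peak_hz = max_hz = None
    if annotation.call_type == "chirp":
        # whole-call spectral extrema on the fundamental contour only
        if f0.contour_hz.size:
            lo = max(float(f0.contour_hz.min()) * 0.85, 1.0)
            hi = min(float(f0.contour_hz.max()) * 1.15, trial_clip.rate / 2 * 0.99)
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=trial_clip.rate, output="sos")
            fund = AudioClip(signal.sosfiltfilt(sos, call_clip.samples), trial_clip.rate)
            try:
                min_hz, peak_hz, max_hz = spectrum_extrema(averaged_psd(fund), edge_db=edge_db)
            except MeasurementError:
                flags.append("no_spectrum_extrema")
    else:
        try:
            min_hz, peak_hz, max_hz = spectrum_extrema(call_psd, edge_db=edge_db)
        except MeasurementError:
            flags.append("no_spectrum_extrema")

    f0_ref = float(np.median(f0.contour_hz)) if f0.contour_hz.size else None
    if f0_ref is not None:
        try:
            peaks = harmonic_peaks(call_psd, f0_ref, K_MAX[annotation.call_type])
            tilt = tilt_ratio(peaks, k_tilt)
            if tilt is None:
                flags.append(f"harmonic_{k_tilt}_not_detected")
        except MeasurementError:
            flags.append("no_fundamental_peak")

    meas = CallMeasurements(
        call_id=annotation.call_id, call_type=annotation.call_type,
        source_level_db=level_db, level_reliable=reliable,
        duration_s=whole_s, syllable_durations_s=syl_s,
        min_freq_hz=min_hz, peak_freq_hz=peak_hz, max_freq_hz=max_hz,
        f0_min_hz=f0.f0_min_hz, f0_peak_hz=f0.f0_peak_hz,
        tilt_ratio=tilt, tilt_harmonic=k_tilt, flags=flags,
    )

    if annotation.call_type == "CLC":
        whistles = [s for s in annotation.syllables if s.type == "whistle"]
        if whistles:
            levels, peaks_hz, durs = [], [], []
            for s in whistles:
                seg = trial_clip.segment(s.onset_s, s.offset_s)
                ps, rel = noise_subtracted_rms(seg, noise_stats.mean_square)
                if not rel:
                    flags.append("whistle_level_unreliable")
                levels.append(ps)
                spsd = averaged_psd(seg)
                if noise_stats.psd is not None:
                    spsd = subtract_psd(spsd, noise_stats.psd)
                peaks_hz.append(float(spsd.freqs[int(np.argmax(spsd.power))]))
                durs.append(s.duration_s)
            meas.whistle_level_db = trial_source_level(levels)
            meas.whistle_peak_hz = float(np.mean(peaks_hz))
            meas.whistle_durations_s = durs
    return meas
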