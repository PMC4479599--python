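# Methods

`lombardlab` models a captive noise-playback experiment on cotton-top
tamarins (*Saguinus oedipus*): subjects vocalize inside a test chamber while
band-limited white noise plays at calibrated levels, and the question is
which acoustic parameters of their calls — amplitude, duration, fundamental
frequency, spectral tilt — shift with noise level and noise bandwidth.
Because no raw recordings from such a study are available, the package pairs
a synthetic-call generator with known effect sizes against the full
measurement and statistics chain, so every measured quantity has ground
truth.

## Experiment structure

The simulated design mirrors the study layout: each subject receives six
sessions, each consisting of one control trial and one treatment trial, for
12 trials per subject. The treatment bank crosses two bandwidth classes —
narrowband (1.5–6.5 kHz, 5 kHz wide, aimed at the perceptually dominant low
harmonics of long calls) and broadband (0.1–10 kHz) — with three in-cage
levels, by default {64, 54, 44} dB re 20 μPa rms over a 42 dB ambient floor
(2–22 dB of noise excess). Only the endpoints of the level range are pinned
down by the study conditions; the 54 dB midpoint is the package's default
and is configurable. Treatment order is randomized per subject under the
experiment seed.

Trials default to 60 s rather than the study's 12 minutes: a desk-scale
length that still holds a full complement of calls plus the 5 s call-free
window the noise estimator needs. All problem sizes below (replicate counts,
calls per trial) were chosen on the same principle — large enough for stable
estimates at a few minutes of total compute.

## Call synthesis

Two call types are generated.

* **Combination long call (CLC)** — one short high-frequency chirp syllable
  followed by four tonal whistle syllables separated by ~0.1 s pauses
  (≈2.3 s total). Whistle fundamentals sit at fixed multipliers
  (1.00/1.05/1.10/1.16) of a per-subject base f0 near 1.6 kHz, consistent
  with published per-subject control minima of roughly 1.4–1.7 kHz. The
  multipliers keep neighbouring fundamentals ≥ ~80 Hz apart so their
  analysis mainlobes do not merge in the averaged spectrum, which would bias
  the tilt ratio. Whistles carry eight harmonics with power weights
  (1, 2.5, 0.8, 0.4, 0.2, 0.1, 0.05, 0.02): the second harmonic dominates,
  with 2–3× the fundamental's energy, matching the reported control-call
  spectral balance.
* **Chirp** — a single ~54 ms upsweep (the published mean control duration
  for one subject) with a weak second harmonic. The sweep runs 8→11 kHz; the
  upper end is kept at 11 kHz so the second harmonic (≤ 22 kHz, plus
  response shifts) stays below the 24 kHz Nyquist frequency — a 12 kHz
  fundamental would alias exactly the harmonic the tilt measurement needs.

Syllables are additive harmonic stacks `Σ_k √w_k sin(2π k φ(t))` with `φ`
the integrated linear f0 sweep, 5 ms raised-cosine ramps, scaled exactly to
an rms level in dB re 20 μPa. `harmonic_weights` are **power** weights, so
for steady tones the programmed spectral-density ratio between harmonics is
the weight ratio itself.

### Noise-response model

`ResponseModel` holds the generator-side effect sizes, all acting on
Δ = noise level − ambient (dB):

| parameter | CLC default | chirp default | meaning |
|---|---|---|---|
| `lombard_slope` | 0.5 dB/dB | 0.25 dB/dB | Lombard amplitude gain |
| `lombard_bw_interaction` | 0.1 dB/dB | 0 | extra slope under broadband noise |
| `duration_slope_ms_per_db` | 0 | 0.45 ms/dB | chirp lengthening (≈5.5 ms at the mean 12 dB excess) |
| `peak_f0_slope_hz_per_db` | 8 Hz/dB | 8 Hz/dB | upward shift of non-minimum whistle f0s / sweep top |
| `min_f0_shift_broad_hz` | −100 Hz | 0 | minimum-f0 shift under broadband noise |
| `min_f0_shift_narrow_hz` | +50 Hz | 0 | minimum-f0 shift under narrowband noise |
| `tilt_slope_per_db` | 0.16 /dB | 0 | growth of the harmonic-k/fundamental energy ratio |

The defaults reproduce the qualitative response signature of the study:
a strong Lombard effect slightly larger under broadband noise, a tilt ratio
rising from ~2.5 toward ~6 at the loudest treatments, a bandwidth-dependent
minimum-f0 shift (down in broadband, up or flat in narrowband), chirp
lengthening, and no chirp tilt change. The minimum-f0 shift is a flat
offset rather than a slope because only per-treatment differences are
published; it is applied to the lowest whistle, while the peak-f0 slope
moves the others. Tilt changes rescale all harmonics above the fundamental
jointly so the measured harmonic's ratio lands exactly on the programmed
value.

### Variability

Published results note high inter- and intra-individual variability without
giving distributions. Per-call jitter defaults: additive normal on level
(σ 1.5 dB, i.e. lognormal in pressure), shared fractional normal jitter on
durations (cv 0.05) and fundamentals (cv 0.02), and a shared lognormal
factor (cv 0.15) on all harmonic/fundamental ratios. Subjects get baseline
offsets of σ 2 dB in level and 3 % in f0. All of these are configurable
stand-ins, not estimates.

### Truth values for swept calls

The tilt measurement reads spectral *density* at harmonic peaks. For a
swept fundamental each harmonic's energy spreads over k× the sweep extent,
so the expected measured density ratio is the power-weight ratio divided by
the relative spreading (sweep extents broadened by the analysis bandwidth,
≈64 Hz at the default window). For the flat-f0 whistles this correction is
exactly 1; for chirps it is ≈ 1/k. The truth table records this expected
value, which the closure suite verifies to within a few percent.

## Measurement chain

* **Levels.** Trial background noise is the first 5 s call-free window's
  mean square; call received level is `sqrt(ms(call) − ms(noise))`, clamped
  at a floor and flagged unreliable below ~3 dB SNR rather than raising.
  Trial source level averages per-call rms values in linear pascals *before*
  converting to dB. "Source level" means received level at the calibrated
  microphone; no distance back-propagation is applied.
* **Spectra.** Welch averaging with a 1024-point Hamming window, 75 %
  overlap and a 4096-point DFT. The 4× zero-padding is deliberate: the
  analysis is specified by its 11.7 Hz bin spacing, which a 1024-point
  window at 48 kHz (46.9 Hz) cannot provide alone. Noise spectra are
  subtracted per bin with a floor at 10⁻¹² of the spectrum peak.
* **Harmonics and tilt.** Harmonic peaks are band maxima within ±15 % of
  k·f0 (f0 from the tracked contour). The fundamental must clear the
  spectrum-wide median floor by 6 dB; higher harmonics below −40 dB re the
  fundamental (window-leakage territory) are treated as absent. Tilt is the
  density ratio harmonic-k/fundamental with k = 3 for CLCs and k = 2 for
  chirps (up to 8 CLC harmonics are recorded; the recorder bandwidth limits
  chirps to 2).
* **Spectral extrema.** "Inflection point" edges are operationalized as the
  outermost crossings of peak − 24 dB on a 5-bin median-smoothed spectrum;
  the threshold is configurable. This is a reproducible proxy for a manual
  spectral-edge reading, and guarantees min ≤ peak ≤ max.
* **Fundamental frequency.** The contour is the per-frame spectral argmax
  inside a band around the fundamental (800–2600 Hz for CLC whistles —
  capped below the dominant second harmonic — and 5–16 kHz for chirps),
  tracked over whistle syllables for CLCs and the whole call for chirps.
  The fundamental is then isolated by a zero-phase band-pass around the
  contour range; peak f0 is the argmax of its PSD and minimum f0 its lower
  −24 dB edge, measured with a 4096-point window when the material is long
  enough so the skirt of a steady tone stays within ~2 bins.
* **Durations.** Whole-call duration includes inter-syllable pauses;
  per-syllable durations exclude them. Annotations are authoritative — the
  core path performs no call detection.

## Statistics

The unit of analysis is the trial mean (source levels averaged in linear
pascals). Each response is fit as

    response ~ noise_db * bandwidth,   random intercept per subject

by REML (statsmodels `MixedLM`), with noise level continuous (controls enter
at the measured ambient level) and bandwidth a two-level factor under sum
coding. Control trials inherit the bandwidth class of their session's
treatment trial — the only reading under which the bandwidth term has 1
numerator df and a complete 3-subject × 12-trial design has 30 denominator
df. Per-term F statistics are Wald tests on the fixed effects; denominator
df is containment-style, `n − rank[fixed design + subject indicators]`,
derived from the realized design rather than hard-coded, so missing cells
(a subject producing no chirps in some trials) shrink it automatically.
Missing cells are omitted, never imputed. Responses are standardized
internally before fitting for numerical stability (F and p are invariant;
the slope is rescaled back). A random subject slope is deliberately not
included: three subjects cannot support one, and the single printed
denominator df implies the simpler structure.

Calibration at the defaults (parameter-level simulation, 3 subjects × 12
trials, 4 CLCs + 6 chirps per trial): the noise-level term's type-I error
over 200 null replicates falls in [0.02, 0.10] at α = 0.05; with a
programmed Lombard slope of 0.4 dB/dB the mean recovered slope over 100
replicates is within ±0.05 with power ≥ 80 %. Statistical calibration runs
on the generator's truth tables without audio rendering; the audio
measurement chain is validated separately by the closure and robustness
suites. Rendering hundreds of replicate experiments to audio would add
nothing but runtime, since the closure suite already bounds the
measurement error far below the between-call jitter.

## What the synthetic data does and does not show

The generator produces strongly harmonic, stationary-background scenes:
ideal band-limited Gaussian noise beds, exactly annotated calls, no
reverberation, no playback-system coloration, no cage noise, no overlapping
vocalizations, and linear response models with Gaussian jitter. Passing
tests therefore demonstrate that the measurement procedures and the ANCOVA
recover known effects under those idealized conditions — they do not
validate performance on real recordings with manual annotations, non-ideal
noise, or non-harmonic calls. The worked-example suite, by contrast, checks
pure arithmetic on the published summary tables and is independent of the
generator. Published F statistics themselves are not reproducible without
the raw recordings; the pipeline instead reproduces the design's degrees of
freedom and the qualitative significance pattern under matching effect
sizes.

## Numerical choices and degenerate inputs

* Noise over-subtraction clamps at a floor and flags, since negative power
  has no physical reading.
* Aliased harmonics are dropped at synthesis with a logged warning; tilt
  adjustments that would drive weights negative clip at zero with a warning.
* Clips shorter than one analysis window fall back to a single zero-padded
  segment with a warning.
* The band-pass corner frequencies of the stimulus filter are pre-warped by
  `(√2−1)^(1/2n)` so the −3 dB points of the forward-backward (squared)
  response land on the nominal band edges.
* Ties in spectral argmax resolve to the lowest-frequency bin (NumPy
  argmax convention); annotation intervals are half-open `[onset, offset)`.
* Placement of calls within a trial reserves an 8 s call-free lead-in so a
  5 s noise window always exists, and raises if the configured call density
  cannot fit without overlap.
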