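# Methods

`ammod` implements, end to end, the computational machinery used to study
how amplitude-modulated background music interacts with sustained
attention: modulation-domain acoustic analysis, controlled insertion of
amplitude modulation into music, stimulus–brain phase-locking analysis of
EEG, and signal-detection scoring of the Sustained Attention to Response
Task (SART), together with synthetic-data generators that close the
parameter-recovery loop for every analysis.

## Modulation-spectrum analysis (`ammod.modspec`)

The waveform (stereo averaged to mono) is decomposed by a bank of 32
gammatone filters with center frequencies equally spaced on the ERB-number
scale between 50 Hz and 8 kHz. The filters are 60-ms FIR gammatone kernels
applied by FFT convolution; the IIR form of the same filters is numerically
unstable in transfer-function coefficients at low center frequencies, and
the FIR kernels are exact to within the truncated impulse-response tail.
Each channel's envelope is the magnitude of the analytic signal, obtained
in the same spectral pass (input FFT × kernel response × one-sided
step), then lowpassed at 150 Hz with a zero-phase raised-cosine spectral
mask and decimated to 400 frames/s — enough to represent 0–100 Hz envelope
fluctuations with a factor-two margin.

Modulation spectra are Welch-averaged periodograms of the demeaned
envelopes (Hann windows, 8-s segments, 50% overlap → 0.125 Hz resolution on
a 30-s excerpt), restricted to 0–100 Hz. By default each channel is
normalized by its squared mean envelope (`normalization_tag="dc_norm"`),
which makes the spectrum invariant to overall level; raw power
(`"none"`) is also supported. The broadband modulation spectrum is the sum
over cochlear channels, so conservation (broadband = column sum) holds by
construction.

**Depth metric.** The applied-modulation depth of a processed track is
quantified as the channel-summed difference between the processed and
original DC-normalized modulation spectra, integrated over ±1 Hz around the
modulator rate (trapezoid rule on the Welch grid). The metric is zero for
identical inputs and monotone in nominal depth for non-degenerate music.

**Band-confinement bookkeeping.** Whether modulation changes are confined
to the intended audio band is judged on the *raw-power* difference map:
with per-channel DC normalization every channel carries equal weight, so
the two near-silent gammatone channels whose skirts straddle the band edges
would dominate the fraction (~10%) regardless of how sharp the band
splitting is. The raw-power fraction weights channels by the envelope
energy actually moved, which is the physically meaningful measure; it also
requires about 1-ERB channel spacing (≈32 channels over the full range) to
be stable, since coarser banks lump boundary and in-band energy together.

## Stimulus generation (`ammod.stimgen`)

The modulator is a raised sinusoid, `m(t) = (1 − d/2) + (d/2)·cos(2π·r·(t −
t₀))`, with unity peaks anchored to the metrical grid of the music (at 120
bpm, rates of 8/16/32 Hz correspond to 16th/32nd/64th notes; being integer
multiples of the 2 Hz quarter rate, the peak set of a slower rate is a
subset of every faster rate's peaks). At full depth (d = 1) the troughs
drive the in-band sound energy to zero; the peak level is depth-invariant.

Modulation is applied only to the 200 Hz–1 kHz region: the signal is split
into in-band and out-of-band components by a zero-phase FFT mask with
raised-cosine transitions (±10% of each edge); the complement is formed by
subtraction, so the split sums to the input exactly and the out-of-band
component passes through bit-identically.

**Spectral-balance preservation.** Multiplying by `m(t)` lowers long-term
in-band power by `(1 − d/2)² + d²/8` (≈ −2 dB at medium depth) and, because
the music's events sit on the modulator peaks, the loss differs across
sub-bands; sidebands at multiples of the rate also leak into neighboring
quiet third-octave bands. The modulated component is therefore rescaled per
standard third-octave sub-band (sharp FFT-bin boundaries — the correction is
a long-term gain, so edge ringing is irrelevant) back to the unmodulated
component's band power. This makes the processed track match the original's
audio spectrum ('EQ') within a fraction of a dB while leaving the temporal
modulation structure intact, which is precisely the stimulus property the
validation report checks: third-octave long-term spectrum deviation ≤ 1 dB
over 100 Hz–8 kHz, modulation-difference map peaking at the applied rate,
and ≤ 5% of raw modulation-difference energy outside the application band.

**Depth calibration.** Nominal depth is not a meaningful unit across music,
so the low/medium/high conditions are calibrated: with the high level
pinned at d = 1, the lower levels are found by bisection so that the depth
metric forms an arithmetic progression (k/n of the full metric; bisection
tolerance 1–2% relative). A silent or modulation-free input raises a
calibration failure. For a single-level request the convention is the depth
whose metric is half the full-depth metric.

**Sessions.** Condition variants are full-session-length, time-aligned
renderings of the same underlying music. A session slices the shared
timeline into equal blocks, playing one variant per block with
raised-cosine amplitude-complementary crossfades (weights summing to one —
the appropriate convention for fully correlated program material; a
w₁² + w₂² = 1 fade would boost identical content by up to 3 dB). Playback
position is therefore continuous across transitions and crossfading a
variant into itself is an exact identity. Assembled stimuli are
peak-normalized to 0.5; because modulated variants have higher crest
factors, the unmodulated variant retains the highest rms after
normalization.

## Stimulus–brain phase locking (`ammod.coupling`)

The stimulus signal entering the coupling analysis is the broadband
cochlear envelope (channel-summed cochleagram) resampled to the EEG rate —
filtering raw audio at 1–50 Hz would capture near-DC pressure rather than
perceptual modulation. EEG and stimulus envelope are filtered with complex
Morlet wavelets at every integer frequency from 1 to 50 Hz (7 cycles by
default, configurable), and the instantaneous phase is the analytic-signal
angle; samples within three cycles of the recording edges are excluded.

The phase-locking value is the magnitude of the *mean* complex phase
difference, `PLV = |N⁻¹ Σ exp(i(φ_EEG − φ_stim))|`, normalized by the
sample count so PLV ∈ [0, 1] regardless of recording length. PLV is
invariant to constant phase offsets and to amplitude scaling of either
signal.

**Null behavior.** For independent signals the null PLV follows the
Rayleigh statistic with an *effective* sample count of roughly T·f/n_cycles
(the narrowband phase decorrelates over about one wavelet length), giving a
null mean near `√(π/4)/√(T·f/n_cycles)` — about 0.15 at 1–4 Hz for a 60-s
recording and below 0.1 only above ~26 Hz. Tests bound the null spectrum by
this frequency-dependent expression rather than a flat threshold.

**Frequency resolution.** Components spaced 1 Hz apart (e.g. 14 and 16 Hz)
cannot be resolved at the default 7-cycle bandwidth (σ_f ≈ f/7 ≈ 2 Hz
there); recovering such structure as distinct local maxima requires ~28
cycles (σ_f ≈ 0.5 Hz), which the 1-Hz-bin spectrum supports on recordings
of a minute or more.

**Binned effect sizes.** Two PLV spectra are compared after averaging over
a named montage group set (10-20 label prefixes; default frontal + central
+ parietal) by Cohen's d paired across frequency-bin centers: centers at
multiples of 4 Hz (capturing the note-rate harmonics and modulation rates)
versus every 1-Hz bin. A zero-variance difference yields a ±inf flag rather
than a number.

**Early-vs-late change.** The recording is cut into contiguous 10-s epochs
(phases from the continuous filtering, so only recording-edge samples are
lost); epoch-wise PLV at the frequency of interest is split into early and
late halves (each half must retain ≥ 30 s), compared per channel with
Welch t-tests, and corrected across channels with Benjamini–Hochberg FDR at
q = 0.05.

## SART behavior (`ammod.behavior`)

Schedules present digits for 250 ms followed by a 900-ms mask (1150 ms
onset asynchrony); 10% of trials show the withhold target 0, placed with an
exact count and no two targets adjacent (drawn exactly via the
stars-and-bars bijection), other digits uniform on 1–9. Presets cover the
6 × 200-trial and 4 × 270-trial designs.

Scoring is standard signal detection: go+press = hit, go+no-press = miss,
no-go+press = false alarm, no-go+no-press = correct rejection; d′ = z(hit
rate) − z(FA rate) with the log-linear correction (+0.5 per count, +1 per
total), tagged in the summary. Note that under this correction the
all-press case cancels to d′ = 0 only when go and no-go counts are equal;
on the SART's 9:1 ratio a small positive residual remains. RT variability
is the sample-SD/mean coefficient of variation per 10-trial window, with
windows containing fewer than two RTs reported as missing.

Condition effects are expressed as d′ differences relative to the
no-modulation baseline, per subject × condition × block; group summaries
carry Cousineau–Morey within-subject SEMs (subject-mean-centered data,
inflated by √(m/(m−1)) for m cells).

**Interaction contrast.** The rate × block × attentional-difficulty effect
is estimated per subject as c = Σ q(rate)·l(block)·Δd′ with quadratic
weights (−1, +2, −1) over 8/16/32 Hz and linear weights (−1, +1) over
early/late blocks (the baseline cancels exactly because Σq = 0). The
statistic is the OLS slope of c on mean-centered ASRS score; inference is
by permutation of the ASRS labels (seeded, default 2000 permutations,
two-sided). This deliberately re-operationalizes a repeated-measures
mixed-effects ANOVA whose exact specification (error strata, software
defaults) is not recoverable; the permutation test is exact under
exchangeability and its type-I calibration is verified by simulation.

## Synthetic data (`ammod.synth`)

Generators are pure functions of configuration + seed; per-stage seeds fan
out from a root seed through a counter-based scheme (CRC of the stage name
into a `SeedSequence` spawn key), so adding a stage never perturbs another
stage's stream.

- **Music**: layers of decaying pentatonic tone bursts (fundamental + two
  harmonics) on the metrical grid at 120 bpm (quarter/8th/16th by default)
  over a −34 dB pink-noise bed, peak-scaled to 0.9. It reproduces the
  features the analyses need — metrical event structure, 200–1000 Hz
  energy, a realistic spread of spectral content — but none of the musical
  qualities (melody, instrumentation, mixing) of real tracks, so passing
  tests say nothing about esthetics, only about the signal chain.
- **Pink noise**: spectral shaping of white noise by f^(−α/2); α = 1 gives
  the −3 dB/octave slope checked over 100 Hz–4 kHz, α = 0 the white
  control.
- **EEG**: each channel is a sum of components `w·s·g(t)·cos(φ_f(t) + θ_ch)`
  phase-locked to the stimulus envelope's narrowband phase φ_f, plus 1/f^α
  noise scaled to a target broadband SNR (0 dB default). φ_f is extracted
  with a deliberately narrow 28-cycle wavelet: with a wide filter, a
  component placed where the envelope is weak would inherit the phase — and
  hence the frequency — of a strong spectral neighbor. The drift parameter
  ramps component gain linearly (drift = 1 → 0.5× to 1.5×) to emulate
  coupling that strengthens or fades over a session. The default 250 Hz
  sampling rate comfortably supports 1–50 Hz analyses. No volume
  conduction or head geometry is modeled; channel topography is just a
  per-component weight vector.
- **Cohort**: a signal-detection agent presses when trial evidence exceeds
  a fixed criterion (evidence ~ N(d′, 1) on go, N(0, 1) on no-go), with
  per-cell d′ = baseline + condition offset + block slope · l(block) +
  interaction · z(ASRS) · w(condition) · l(block). Defaults (baseline d′ =
  2.5, criterion 0.2) give ~99% hits and ~42% false alarms, the
  near-ceiling hit / frequent-commission-error regime typical of SART. ASRS
  scores are a discretized truncated normal over the instrument's 0–72
  range (mean 31, SD 12); RTs are lognormal (median 0.35 s, σ = 0.25).
  A counts-level path (`synth_cohort_counts`) draws the per-cell binomial
  counts directly — distributionally identical to scoring the trial-level
  logs, used for large calibration studies.

Note that in the near-ceiling regime the log-linear correction shrinks
high hit rates noticeably at a few hundred trials per cell, so recovered
condition effects are attenuated relative to the generator's nominal d′
offsets; the unbiasedness checks therefore run in a moderate-sensitivity
regime (baseline 1.5, criterion 0.5) at 1,000 trials per cell.

## Problem sizes and numerical choices

Tests run the acoustic chain on 12–30 s excerpts (12-s fixtures at 16 kHz
with a 20-channel bank for unit tests; 30 s at 22.05 kHz with the standard
32-channel bank for the headline recovery checks), 60-s EEG simulations at
250 Hz, and cohorts of 16–82 subjects; the type-I calibration uses 2,000
scaled-down cohorts with 399-permutation tests (whose achievable level is
exactly 20/400 = 0.05). Peak finding breaks ties toward the lower
frequency. Degenerate inputs (silence, empty ranges, below-floor difference
maps, zero-variance effect sizes) raise typed errors or carry explicit
flags rather than returning numbers.

## Known limitations

- The synthetic music's modulation spectrum is far more regular than real
  music; calibration and validation behavior on commercial recordings may
  differ in degree (not in kind).
- The EEG generator's components are perfectly envelope-locked by
  construction; real entrainment is intermittent, so PLV magnitudes here
  are upper bounds, and recovery rates quantify the analysis chain, not
  physiology.
- The permutation-contrast inference answers the same question as a
  mixed-effects ANOVA but is not numerically comparable to F statistics
  from specific ANOVA software.
- EEG preprocessing (referencing, artifact correction, channel
  interpolation) is out of scope; inputs are assumed clean.
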