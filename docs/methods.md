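# Methods

This note documents the models, conventions, and numerical choices behind
cardiokit, and what its synthetic-signal tests do and do not demonstrate.

## Signal model and pipeline

The toolkit analyzes heart-rate variability (HRV): the beat-to-beat
fluctuation of the intervals between successive heartbeats, driven by the
sympathetic and parasympathetic branches of the autonomic nervous system.
Input is either a raw single-channel waveform (ECG or PPG) with a known
sampling rate, or a pre-extracted list of RR intervals in milliseconds.
The processing chain is:

1. **Denoising** — zero-phase frequency-domain band-pass with raised-cosine
   transitions (ECG: zero below 0.5 Hz and above 40 Hz, flat 1–35 Hz;
   PPG: zero below 0.5 Hz and above 10 Hz, flat 0.9–8 Hz). An FFT mask is
   used instead of an IIR filtfilt because it is exactly zero-phase (no
   fiducial-point shift) and leaves no multi-second edge transients from a
   0.5 Hz high-pass on short records; the cost is mild Gibbs ripple around
   very sharp deflections, irrelevant at these transition widths.
2. **Beat detection** — a Pan–Tompkins-style chain for ECG R peaks:
   zero-phase 5–15 Hz band-pass, derivative, squaring, 150 ms
   moving-window integration, adaptive dual thresholds
   (`NPK + 0.25 (SPK − NPK)` with exponential updates), a 200 ms refractory
   period, and refinement of each fiducial to the local maximum of the
   baseline-free signal within ±50 ms. All thresholds are relative, so
   detection is invariant to positive amplitude scaling. PPG systolic peaks
   use the same adaptive-threshold machinery on the squared positive part of
   a 0.5–8 Hz band-passed signal with a 300 ms refractory period.
3. **RR extraction and NN filtering** — intervals are differences of
   adjacent beat times. An interval is "normal-to-normal" (NN) if it touches
   only sinus-labelled beats, lies within physiologic bounds
   (default 300–2000 ms), and deviates less than 20% from the running median
   of the last 11 accepted intervals (seeded by the leading in-bound
   intervals). Rejections split the series into segments; successive-difference
   statistics never pair intervals across a gap, so one ectopic can never
   inject two spurious large differences.
4. **Uniform tachogram** — natural cubic-spline interpolation of
   (interval end time, interval length) evaluated on a 2 Hz grid between the
   first and last beat (no extrapolation). The mean is retained; spectral
   estimators remove it themselves.

## Time-domain indices

Mean RR, SDNN, SDANN, SDindex, RMSSD, NN50, pNN50, instantaneous heart-rate
extremes, and the geometric indices. Conventions: sample (N−1) standard
deviations; NN50 counts successive differences strictly greater than 50 ms;
instantaneous HR is 60000/NN bpm and HRmin/HRmax/MeanHR are its extremes and
mean after NN filtering (a smoothing window is deliberately not applied;
filtering already removed artifactual extremes). SDANN and SDindex use
non-overlapping 5-minute windows laid out by clock time from the first beat,
each needing at least 10 intervals, and are reported absent for records
shorter than two windows.

The NN histogram uses 7.8125 ms bins (1/128 s, the conventional HRV bin
width) aligned to multiples of the width. The HRV triangular index is the
total count divided by the modal bin count. TINN fits a triangle with apex
fixed at the modal bin (ties broken toward the count-weighted mean) and
base endpoints searched exhaustively over the histogram's own bin edges,
minimizing squared error to the counts; TINN is the base width M − N. For a
single-bin histogram this degenerates to one bin width.

## Frequency-domain indices

Spectra are estimated on the mean-removed uniform tachogram three ways:

* **Burg autoregressive model** (default order 16; 16–20 is the standard
  range for 2–4 Hz cardiac tachograms). The lattice recursion picks each
  reflection coefficient to minimize the summed forward+backward prediction
  error, guaranteeing a stable model. With denominator convention
  `A(z) = 1 + Σ a_k z^{-k}`, the one-sided PSD is
  `P(f) = 2 (ε_p / fs) / |A(e^{-2πjf/fs})|²` for 0 < f < fs/2 (endpoints not
  doubled), so the trapezoid integral over [0, fs/2] equals the process
  variance. The PSD is evaluated on a **4096-point** grid: high-order AR
  spectra of strongly periodic tachograms have peaks narrow enough that a
  1024–2048-point grid visibly underestimates their integrated band mass.
* **Welch periodogram** — Hann window, 150 s segments, 50% overlap,
  one-sided density scaling (scipy).
* **Global wavelet spectrum** — the time-average of the Morlet scalogram,
  mapped scale→frequency and rescaled by a single variance-matching constant
  so band integrals are comparable to Welch's.

Band powers integrate the PSD by the trapezoid rule (band edges
interpolated) over ULF 0–0.003, VLF 0.003–0.04, LF 0.04–0.15 and
HF 0.15–0.4 Hz; total power is the integral to 0.4 Hz. ULF is only
meaningful — and only reported — for records of at least an hour.
Normalized units are stored as fractions lf/(lf+hf) and hf/(lf+hf) in
[0, 1]; reference flagging converts them to the percent scale the reference
table is quoted in. A vanishing HF power yields an absent LF/HF ratio with a
warning rather than a division error.

Frequency analysis defaults to a 5-minute segment (the standard short-term
recommendation): the first window in which at most 10% of beats were
rejected, unless a start time is given.

## Time-frequency analysis

* **Windowed Burg dynamics** — per sliding window (default 300 s window,
  60 s step), fit + integrate bands; emits the LF/HF sympathovagal-balance
  ratio at the window midpoint. Windows with HF power below 1e-6 ms² (or
  zero variance) emit no point rather than an infinite ratio.
* **Spectral surface** — the matrix of per-window Burg PSDs (each row
  bit-identical to analyzing that window alone; zero-variance windows give
  zero rows), exportable as CSV matrix plus axis files for 3-D rendering.
* **CWT scalogram** — complex Morlet with ω₀ = 6 (`cmor2.0-0.9549` in
  PyWavelets terms), 64 log-spaced voices between 0.003 Hz and the Nyquist
  frequency; power is the squared modulus. The cone of influence uses the
  standard Morlet e-folding time √2·s (≈ √2/(1.033 f) seconds); points
  closer than that to either record edge are flagged as outside the cone.

## Nonlinear indices

Computed on the NN event series, not the resampled tachogram, because spline
interpolation injects spurious short-range correlation.

* **R/S Hurst exponent** — for ≥8 log-spaced window sizes n between 16 and
  N/4: partition into ⌊N/n⌋ blocks, per block divide the range of the
  cumulative mean-adjusted sum by the block sample SD, average, and take the
  slope of log(R/S) vs log(n). Blocks with zero SD are skipped. On white
  noise the small-sample R/S statistic is known to sit slightly above the
  asymptotic 0.5 (≈0.53–0.56 at N = 8192); tests assert the documented
  [0.45, 0.62] band rather than the asymptote.
* **DFA** — integrate the mean-centred series, tile into non-overlapping
  boxes of size n from both series ends (so trailing samples are used),
  linearly detrend each box, and regress log RMS residual on log n.
  alpha1 covers 4–16 beats, alpha2 16–64, alpha their union — the
  conventional short/long split. Anchors: 0.5 uncorrelated, 1.0 1/f noise,
  1.5 Brownian motion.

Both estimators are affine-invariant by construction.

## Reference flagging, agreement, and group statistics

The packaged reference table transcribes the healthy short/long-term
standard values (SDNN 102–180 ms, SDANN 92–162 ms, RMSSD 15–39 ms,
HRV triangular index 22–52, total power and LF/HF bands, etc.). Entries
quoted only as mean ± sd are given the range mean ∓ sd, the same convention
the time-domain table states explicitly; parameters with no published
reference are flagged `no_reference`. Bounds are inclusive: a value exactly
on the limit is in range.

Cross-modality agreement between paired per-subject index series is
reported two ways: the raw sum of squared differences Σ(xᵢ−yᵢ)², and the
percent relative RMS error 100·√(Σ(xᵢ−yᵢ)²/N)/mean(x), the form used for
modality-comparison tables (the default). Group comparison is the classical
one-way ANOVA F test (scipy), significant at p ≤ 0.05; for two groups it
equals the squared pooled t statistic exactly. Zero within-group variance
with nonzero between-group spread reports F = ∞, p = 0 with a warning.

## Synthetic generators

`generate_rr` builds RR series beat by beat:
`RR_k = mean + Σ a·sin(2πf·t_{k-1}) + N(0, σ)`, with cumulative beat times,
LF/HF tones defaulting to the band centroids 0.10/0.25 Hz. Ectopic couplets
(0.6× premature interval followed by a 1.4× compensatory pause) are injected
at a Poisson rate and labelled, giving exact ground truth for the NN filter.
This is a tone-modulated interval model, not an integral-pulse-frequency
cardiac model: band powers are exactly known (a²/2 per tone), at the cost of
not reproducing IPFM's harmonic structure.

`generate_ecg` renders Gaussian P-QRS-T templates with the R apex exactly on
each beat time plus white noise at a chosen SNR; `generate_ppg` renders an
asymmetric (90 ms rise, 220 ms decay) pulse whose systolic peak sits a
constant pulse-transit offset after the beat, so PP intervals equal RR
intervals identically.

Cohort presets (`healthy`, `heart_failure_like`, `tachycardia_like`) draw
per-subject generator parameters so that disease-like groups have depressed
modulation amplitudes and beat-to-beat noise and tachycardia has the
shortest mean RR, 600 s per subject. They encode directions of effect and
rough magnitudes only — no claim of clinical realism. Consequently, passing
tests demonstrate estimator correctness on signals of known structure
(tones, scaling noise, template beats); they do not validate detector
robustness against real artifact morphology, arrhythmia, respiration-driven
HF migration, or non-stationarity beyond the constructed cases.

`generate_fgn` (circulant-embedding fractional Gaussian noise) and
`generate_power_law_noise` (spectral synthesis) provide sequences with
exactly known scaling exponents for validating the nonlinear estimators.

## Degenerate inputs and tie-breaks

Constant waveforms yield empty beat series (not errors); constant tachograms
yield zero spectral surfaces but are rejected by `fit_burg` (zero variance);
constant NN series are rejected by both scaling estimators (S = 0). Peak
conflicts inside a refractory period keep the larger peak. The TINN modal
tie-break prefers the bin nearer the count-weighted mean. Burg recursion
stops early (remaining coefficients zero) if the prediction error is
exhausted.

## Problem sizes used in the verification suite

Spectral recovery uses 600–1500 s tachograms at 2 Hz; nonlinear recovery
uses sequences of 8192 samples averaged over 5 seeds; detection uses 60-beat
records at 250 Hz (ECG) and 50 Hz (PPG); cohort contrasts use 20 subjects ×
3 seeds per group at 600 s per subject. These sizes put the estimators well
inside their asymptotic regimes while keeping the full suite fast.

## Known limitations

* No multi-lead fusion, beat-morphology classification, or arrhythmia
  diagnosis; the NN rule is purely interval-based.
* No Lomb–Scargle spectrum on irregularly sampled beats; spectra assume the
  2 Hz resampled tachogram, whose spline low-pass slightly attenuates power
  approaching the HF upper edge.
* The wavelet PSD's variance-matching calibration makes band integrals
  comparable, not identical, to Welch's (white-noise LF/HF agrees within
  ~10% in practice).
* Reference ranges describe healthy adults on standard recording lengths;
  flagging 5-minute-segment frequency indices against long-term references
  is a screening heuristic, not a diagnosis.
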