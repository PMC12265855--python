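# Methods

## Problem and model

A laser scanning fluorescence microscope acquiring in xyt mode produces a
time series of frames of one static field of view.  Each frame is modeled
as a fixed scene plus uncorrelated zero-mean noise, optionally attenuated
over time by photobleaching.  Averaging the first n frames suppresses the
noise standard deviation by √n but costs acquisition time and light dose.
The package scores candidate averaging depths on three measurements and
combines them into a recommendation.

**Averaging series.** Levels are the prefix means over 2⁰, 2¹, …, 2^K
frames, K = ⌊log₂ n_frames⌋.  Prefixes (not disjoint blocks or resampled
subsets) are used because they are what a shorter real acquisition would
deliver: one would simply stop scanning after 2^k frames.  Stacks whose
length is not a power of two are truncated to the largest usable prefix
with a logged warning.  Level images stay in float; quantization happens
only at TIFF export (clip to the integer range, then round half-to-even,
so averaged values can never wrap).

**SNR.** For a single image, SNR = μ/σ with σ the population standard
deviation (divisor N; at image pixel counts the N vs N−1 distinction is
far below every tolerance used here).  A constant image is valid
degenerate input: when σ < 10⁻¹² · max(1, |μ|) the function returns the
infinite-SNR sentinel instead of raising, and selection ranks the sentinel
above every finite value.  Note that for structured scenes σ mixes
structural contrast with noise, so the per-level SNR *gain* is far smaller
than √n; the √n law is exact only for a constant base, which is how the
tests measure it.

**Photobleaching.** The per-frame spatial mean I(t) is fitted with
I(t) = a·e^(−bt) + c by bounded least squares (scipy `curve_fit`,
trust-region reflective, tolerances 10⁻¹⁴), with a, b, c ≥ 0 so the fitted
curve is nonincreasing — the model describes decay, and a negative rate
would turn "bleaching" into brightening, which is out of model.  Initial
guesses: a₀ = I(0) − min I, b₀ = 1/n, c₀ = min I.  Solver failure returns
the identity fit (a = 0, b = 0, c = I(0)) flagged `converged=False`, and
the pipeline proceeds uncorrected with a warning.

*Significance gate.*  On data with no real bleaching, sampling noise in
the mean trace always induces a small spurious fitted decay.  Under a
strict bleaching budget (0% is the common choice) that spurious decay
would disqualify almost every frame, which is clearly wrong.  The fitted
exponential is therefore compared against a constant fit with a
nested-model F-test (2 extra parameters, α = 0.05); when the improvement
is not significant the flat fit (a = 0, b = 0, c = mean) is returned with
`decay_significant=False`, making correction and eligibility the identity.
The practical reading: bleaching you cannot detect is bleaching you do not
correct for.

*Correction and eligibility.*  Correction multiplies frame t by the single
scalar (a + c)/(a·e^(−bt) + c); frame 0 is unchanged and within-frame
intensity ratios are preserved.  Frame t is eligible under a bleaching
budget of L percent iff the fitted normalized intensity
(a·e^(−bt) + c)/(a + c) ≥ 1 − L/100 − 10⁻⁹ — the *fitted* curve, not the
raw noisy means, so random fluctuations cannot disqualify individual
frames.  Because the curve is nonincreasing, eligibility is monotone in t.
An averaging level is eligible only if its last (most-bleached)
constituent frame, index 2^k − 1, is eligible: an average contaminated by
over-bleached frames should not be recommended.  Eligibility is always
judged on the *uncorrected* fit — it expresses how much real signal was
lost, which correction cannot restore.

By default SNR and spectral entropy are computed on the bleach-corrected
stack (toggleable), so the decay trend cannot masquerade as an SNR or
spectral change.

**Spectral entropy.** P(u, v) = |FFT₂(image)|² with DC shifted to the
center; no windowing, no detrending, DC included (excluding DC is a flag,
off by default).  Normalizing P to unit sum gives a distribution over M
frequency bins whose Shannon entropy H = −Σ pᵢ ln pᵢ (natural log; the
normalization H_norm = H/ln M makes the base immaterial) is 0 for a
single-bin spectrum and 1 (normalized) for a flat one.  Averaging removes
the flat noise floor, so H_norm decreases with level and plateaus once
only structure remains.

**Plateau detection.** The per-level H_norm series is smoothed with a
centered moving average (default window 5; at the boundaries the window
shrinks symmetrically rather than padding, which matters because the
series has only ~10 points), then min–max rescaled to [0, 1] so the
threshold is scale-free.  The PSD-optimal level is the smallest index
i ≥ 1 from which *every* subsequent step |s[j+1] − s[j]| (j = i … n−2) is
below the threshold (default 0.1) — a sustained plateau, not a first
crossing, because a single small step can occur before true
stabilization.  A constant series returns index 0; if no index sustains
the plateau the last level is returned flagged `no_plateau`.  Raising the
threshold can only move the optimum earlier (monotonicity, property-tested
against a brute-force scan).

**Selection.** SNR-optimal = argmax SNR over eligible levels, ties broken
toward fewer frames, the infinite sentinel ranking above all finite
values; if nothing is eligible, level 0 with a warning.  The headline
recommendation is min(SNR-optimal, PSD-optimal): the published numbers
report both side by side with the PSD choice framed as the economical one,
so the minimum is the conservative acquisition advice.  Both values appear
in every report.

## Synthetic data generator

`make_noisy_series` emulates the reference test dataset: frame t =
envelope(t) · base + i.i.d. N(0, σ²) per pixel, envelope(t) =
(a·e^(−bt) + c)/(a + c) or identically 1.  Defaults follow the reference
conditions: σ = 10 on an 8-bit-range structured base, 2⁹ instances.
Noise is added *after* the envelope because detector noise does not
bleach.  By default frames are not clipped, so the √n law holds exactly;
`clip_range=(0, 255)` emulates 8-bit storage and is used in the
end-to-end replication runs.  Frames are drawn from one seeded generator
in index order, so shorter series are prefixes of longer ones.
`make_phantom` provides a deterministic structured base (gradient +
rectangles + disks + sinusoidal texture, values in [0, 255]) with
frequency content at several scales; it stands in for a real
high-SNR scene and is synthetic by construction.

What the generator does *not* model: Poisson/shot noise and detector
gain, optical blur (PSF), drift and motion, photoswitching, or
non-stationary noise.  Passing tests therefore demonstrate correctness of
the measurements and the selection logic under the stated noise model,
not robustness to live-specimen dynamics — the same caveat the method
itself carries for real use.

## Numerical and design choices

- Eligibility boundary tolerance 10⁻⁹; SNR zero-noise guard
  10⁻¹² · max(1, |μ|).
- Center-crop origin = ⌊(dim − side)/2⌋, 0-based half-open ranges, so
  nested crops compose; "8 pixels in diameter" for a square ROI is read
  as side length 8.
- Integer TIFF input must be nonnegative (raw counts); float32 TIFFs are
  the package's own export format and may contain small negative noise
  excursions from unclipped simulations.
- Multi-channel/RGB pages are rejected, never silently converted.
- The F-test significance level (0.05) and the stability threshold (0.1)
  are the only two "soft" constants; both are user-visible (the threshold
  directly, the gate via `decay_significant` in the report).

## Problem sizes

The end-to-end replication runs use a 512×512 phantom with 2⁹ noisy
instances: large enough that the sample covariance between the scene and
the residual noise (which scales as 1/√N_pixels and is what could scramble
the ordering of the top two SNR levels) stays about 3σ below the level-8
vs level-9 SNR gap, comparable to the reference image geometry.  Unit and
property tests use 32–64 pixel frames and 16–512 frames, where every
tolerance has comfortable sampling margin.

## Known limitations

- The exact entropy normalization and plateau rule of the original
  implementation are not published; the choices above are documented and
  configurable, and the PSD-optimal level on any particular scene depends
  on them (and on the scene), so it is reported rather than guaranteed.
- Acquisition-time arithmetic (frames × lines / line rate) ignores scanner
  flyback and bidirectional timing; no time estimate is emitted.
- Only frame-level (not within-frame line-level) averaging is simulated;
  line-averaged data is analyzed identically at the per-level interface.
- Bi-exponential or stretched-exponential bleaching, and per-pixel
  bleaching correction, are out of scope.
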