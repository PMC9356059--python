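# Methods

`rhythmtag` implements a complete frequency-tagging workflow for measuring
cortical tracking of speech rhythm: stimulus synthesis, an acoustic model
of the expected response, a forward EEG simulator with known ground truth,
preprocessing, spectral measurement, and group-level mixed-model
inference.  This note documents the models, the defaults and why they are
what they are, the numerical choices, and the limits of what the synthetic
data can establish.

## Stimulus model

Every stimulus is a 30 s sequence of 150 consonant–vowel–nasal (CVn)
monosyllables of exactly 200 ms, so the acoustics are periodic at the
5 Hz syllable rate with a sub-syllabic 10 Hz component from the
vowel/nasal alternation (two morae per syllable), and nothing marks the
2.5 Hz foot — foot structure, if perceived, must be imposed by the
listener.  Segment timing is fixed by onset class: stop onsets are 20 ms
followed by an 80 ms vowel; fricative onsets 50 + 50 ms; the nasal coda is
always 100 ms.  The glide onset /j/, whose timing the design leaves open,
uses the 50 + 50 ms split (a continuous voiced onset patterns with the
fricatives durationally).  The inventory is an explicit list of 14 legal
CVn tokens drawn from 10 consonants, 3 vowels and 3 nasals; the token
identities are a package fixture (the design fixes the phoneme sets and
the count, not the list).

Sequences repeat 10 randomly chosen syllables 11 times and the remaining
4 ten times, shuffled under a no-adjacent-repeat constraint.  Full
rejection sampling is impractical here (the expected number of adjacent
repeats in a random shuffle is ~10, so the acceptance probability is
~e^-10); the planner instead shuffles once and repairs violations by
seeded random swaps that never create new ones.  The parity statistics of
the result match unconstrained shuffling, i.e. the repair introduces no
measurable sequential structure.

Syllables are rendered by a source–filter harmonic synthesizer: voiced
segments are harmonic stacks at the voice fundamental (default 180 Hz,
pitch deviants 280 Hz, 16 kHz sampling) with per-harmonic amplitudes set
by a spectral-tilt roll-off and two-formant resonance shaping that
crossfades from the vowel's formants into the nasal murmur; stop onsets
are a silent closure plus a 5 ms burst; fricative onsets are band-shaped
noise (deterministic per voice so waveforms are fully seed-reproducible).
The segment envelope rises quickly into the vowel and decays through the
nasal, giving each syllable one dominant energy peak.  The analyses
downstream depend only on this envelope structure, not on segmental
naturalness — perceptual quality is a non-goal.

The non-speech control is 1-channel noise vocoding: seeded white noise
multiplied by the broadband envelope (rectified signal low-passed at
120 Hz with a 4th-order zero-phase Butterworth, computed over the whole
sequence).  The output is RMS-matched to the input; because a Gaussian
carrier at matched RMS can exceed full scale, the waveform is rescaled to
peak 0.999 when (rarely) needed.  Envelope preservation is quantified as
modulation depth (5 Hz envelope amplitude over envelope mean), which is
carrier-independent; raw envelope amplitudes differ between noise and
harmonic carriers by a constant factor even for a perfect vocoder.

### What "no 2.5 Hz peak" means

Individual random sequences carry chance energy at 2.5 Hz: the even/odd
token split weighted by inter-token envelope differences forms a
heavy-tailed parity sum, intrinsic to any fixed-count no-repeat design.
A single spectral bin is also Rayleigh-distributed around the same
continuum as its neighbours, so "bin ≤ band median" is a coin flip even
for a perfectly foot-free stimulus.  The package therefore tests the
design-level claim on the condition ensemble: on the average envelope
spectrum of 8 sequences, 5 and 10 Hz must stand at >5x and >3x the
neighbour-bin floor while 2.5 Hz stays below 2x it; per sequence, the
5 Hz component must dominate the 10 Hz one.

## Forward EEG model

A simulated participant-condition is a continuous Cz-referenced record
(128 data channels of the geodesic sensor net, 1000 Hz) containing 8
epochs of 30 s with onset markers.  Components:

* **Tracking response** — per target rate f ∈ {2.5, 5, 10} Hz, amplitude
  a × (cos 2πft + Σ_h r_h cos 2πhft): responses to non-sinusoidal
  envelopes are themselves non-sinusoidal, so a configurable harmonic
  profile (default: 2nd harmonic at 0.3) is part of the model.  With
  zero-phase cosines the 2nd harmonic of the 5 Hz response adds
  coherently at the 10 Hz bin; ground truth records both the fundamental
  and the effective bin amplitude.  Amplitudes are drawn per participant
  as mean(group, condition, f) + participant offset (SD 0.12 µV, shared
  across cells — the quantity a random intercept absorbs) + cell noise
  (SD 0.06 µV), clipped at zero.  Default means (µV at the ROI) follow
  the qualitative ordering the design is meant to resolve — 5 Hz:
  english 0.55, french 0.80, japanese 0.50; 10 Hz: 0.28/0.36/0.22 with
  vocoded 10 Hz scaled by 0.65 (a speech > non-speech difference at 10 Hz
  only); 2.5 Hz: 0.  These are configuration, not hard-coded truths: the
  package tests recoverability, not the human result.
* **Spatial projection** — a fixed fronto-central weight vector (Gaussian
  fall-off from the ROI centroid of the montage geometry, floored at
  0.25), normalized so that after average-referencing the mean ROI weight
  is 1; ROI estimates are then on the embedded-amplitude scale.  A dipole
  forward solution would add nothing, since ROI averaging is the only
  spatial operation downstream.
* **Background noise** — 1/f^1 noise per channel (spectral shaping of
  seeded white noise, flat below 0.1 Hz), RMS 15 µV.  This yields a
  single-epoch amplitude-spectrum floor of ~0.5 µV per 0.025 Hz bin near
  5 Hz, i.e. embedded responses are comfortably but not trivially above
  noise after 8-epoch averaging.
* **Ocular artifacts** — rank-1 deflections with a broad frontal
  topography, 150–250 µV peak, 0.5–2 s, on a per-epoch Poisson schedule
  (default 0.8/epoch; per-participant overrides support contamination
  studies).  Every scheduled blink exceeds the ±100 µV rejection
  threshold by construction, so ground-truth flags predict rejection
  exactly when no removal is applied.
* **Bad channels** — each channel is replaced wholesale by white noise of
  7× the background RMS with probability 0.02 (≈2.6 expected bad channels,
  matching a plausible recording).

The fast table-level generator (`simulate_response_table`) draws the same
amplitude model directly as a measured-response table for studying the
group models.  It does **not** clip at zero: it emulates ROI means of
noise-subtracted spectra, which are legitimately negative under the null
(clipping would put a point mass at zero and distort test calibration).

## Preprocessing

Fixed stage order, asserted in tests: band-pass filter → epoch →
bad-channel detection → ocular handling → interpolation → epoch rejection
→ average reference → averaging.

* **Filter**: zero-phase windowed-sinc FIR (Hamming), 0.3–30 Hz.  The low
  edge fixes the length (~13200 taps at 1000 Hz): passband from 0.3 Hz
  with ≥40 dB attenuation at 0.05 Hz; the upper transition runs to well
  under 50 Hz.  Applied as centered convolution (exactly zero phase).
* **Bad channels**: a channel is bad when its MAD-based robust SD exceeds
  the channel-population median by more than k = 5 population MADs
  (replacing visual inspection); more than 12 bad channels flags the
  participant.  Robust SDs are computed on a time-subsample (~2000
  samples/epoch), which pins the scale to ~1% at a fraction of the cost.
* **Ocular removal** is pluggable: `none`, or template regression — the
  blink template is the mean of 11 periocular proxy channels; samples
  where it exceeds 60 µV (dilated 100 ms, cosine-tapered) define the
  support; each channel is regressed on the template there and the fit
  subtracted.  For rank-1 simulated blinks this is exact up to noise;
  real ocular activity is not rank-1, which is why the ±100 µV rejection
  rule remains the backstop the acceptance tests rely on.
* **Interpolation**: inverse-distance-squared weighting of the 4 nearest
  good channels (montage geometry).  Spherical splines would differ
  imperceptibly at the ROI-mean level; the weighting is an explicit,
  exactly testable rule.
* **Rejection**: an epoch is rejected when any sample on a
  non-interpolated channel strictly exceeds 100 µV (a sample at exactly
  100 µV survives: the rule is "exceeding").  Fewer than 6 of 8 accepted
  epochs excludes the participant-condition.  Rejection runs after
  interpolation by default (flag to swap).
* **Reference/averaging**: channel-mean subtraction per sample, then the
  mean of accepted epochs.

## Spectral measurement

The 30 s evoked average is zero-padded to 40 s and Fourier-transformed:
0.025 Hz bins from 0 to 500 Hz, scaled 2/N_signal so a unit sinusoid at a
bin center reads 1.0 µV.  The 0.025 Hz resolution printed by the
procedure requires this 4/3 padding (30 s alone gives 0.033 Hz); padding
factor is configurable.  Two noise-correction constructions:

* **Baseline subtraction**: per bin, subtract the mean amplitude at
  offsets ±2..12; signal-free bins then average to zero.  Edge bins use
  the available side and are flagged.  Note an inherent ~5% low bias on
  true peaks: the padded spectrum is oversampled, so a bin-centered
  sinusoid leaks ~5.4% of its amplitude into its own baseline
  neighbourhood.  Correlation-based recovery is unaffected.
* **z-scores** at 2.5/5/10 Hz on the ROI-averaged spectrum: target bin
  minus the mean of 20 neighbours (10 per side at offsets 2..11, skipping
  the immediately adjacent bin), over their sample SD; z > 3.1 (one-tailed
  p < 0.001) marks a significant response.  The stated 0.50 Hz span and
  the adjacent-bin exclusion are mutually inconsistent by one bin
  (±2..11 spans 0.275 Hz per side); both readings are implemented
  (`z_span_mode`), defaulting to the adjacent-excluded one.

The response magnitude is the mean corrected amplitude over a 10-channel
fronto-central ROI.  The electrode identities are a documented default
(`E4 E5 E6 E7 E12 E13 E30 E105 E106 E112`) and overridable, since the
source figure highlights but does not enumerate them.

## Group statistics

All models: standardized amplitude (z-transformed within the model's
analysis subset; a flag switches to global standardization), simple-coded
factors (each level vs. reference, centered — estimates are
level-minus-reference differences and the intercept is the grand cell
mean), random intercept per participant (the documented endpoint of
slope-removal-until-convergence), REML.

* Cross-language: Amplitude ~ Frequency + Group + Frequency×Group on the
  three pooled speech voices at 5 and 10 Hz, with pairwise group
  contrasts at each frequency and within-group frequency contrasts.
* Speech/non-speech: Amplitude ~ Frequency × Group × Stimulus on the
  unfamiliar voice vs. its vocoded control, then per-frequency sub-models
  with per-group speech−non-speech contrasts.
* Harmonic regression: 10 Hz amplitude ~ Group + 5 Hz amplitude, matched
  by participant × condition; the 5 Hz slope is also reported
  back-transformed to the µV scale.

Estimation is delegated to statsmodels' MixedLM; fixed-effect covariances,
Satterthwaite degrees of freedom and omnibus F tests are computed from the
closed-form random-intercept GLS algebra: Var(c'β̂) as a function of the
two variance components, its gradient by central differences, and the
variance-component covariance from the numerical Hessian of the REML
criterion; multi-df denominators follow the eigencontrast construction.
On the reference fixture the entire output (β, SE, df, F, p, variance
components) matches lme4 + lmerTest to ≤1e-3.  Degenerate inputs
(zero residual variance) fall back to the OLS solution with residual df.
Follow-up contrasts use α = 0.05 with no multiplicity correction,
mirroring standard reporting practice in this literature — a deliberate
choice, not a recommendation.

The power criterion ("a 1 SD group effect at n = 20/group is detected in
≥90% of runs") defines 1 SD as the SD of the amplitude variable over the
cross-language analysis set — one unit of the standardized scale the
models operate on (~0.18 µV under the null configuration).

## Problem sizes and tolerances

Defaults are the study conditions (24 participants/group, 8 epochs, 128
channels).  The verification suites run reduced but statistically
meaningful sizes chosen as the smallest that pin each property down:
sequence invariants over 1000 seeds; detection calibration over 200
simulated condition-averages (pass bound ≤0.005 false positives, nominal
0.001, margin for spectral leakage between correlated padded bins);
parameter recovery over 20 forward-simulated participants (r ≥ 0.9);
model calibration over 500 null tables (5% ± 2%) and power over 100
effect tables; the orchestrated end-to-end determinism check uses 3
groups × 2 participants × 3 conditions.  Raw-spectrum calibration is
asserted at 1%; corrected amplitudes at 7% (the leakage bias above);
filter passband at 1%.

## What the synthetic data do and do not show

The generators emulate the statistical skeleton of the experiment —
periodic responses plus 1/f noise, rank-1 blinks, high-variance channels,
participant-level amplitude variation with a configurable qualitative
group ordering.  They do not emulate: dipolar source geometry
(the spatial weight is a fixed profile), non-stationary or
phase-jittered tracking, non-rank-1 ocular activity, line noise, drifting
electrodes, or any perceptual/linguistic process.  Passing tests
therefore establish that the *pipeline* is correct and calibrated — that
embedded effects of the configured size are recovered and null effects
fire at nominal rates — not what a human cohort would show.  Group-level
statistics of real human recordings are outside what simulation can
reproduce and are out of scope here.
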