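# Methods

`multisync` implements a complete in-silico version of a multiplexed
auditory-synchronization paradigm: stimulus synthesis, task logic, a
generative model of the EEG it should evoke, and the analysis chain that
recovers synchronization at every timescale. This note records the model,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Stimulus model

**Target.** The target is a stream of sinusoidally amplitude-modulated
(SAM) tone tokens. All rates are integer multiples of one base rate
f₀ = 6.8 Hz: the carrier is 76·f₀ = 516.8 Hz and the five AM rates are
{4, 6, 8, 10, 12}·f₀ = 27.2, 40.8, 54.4, 68, 81.6 Hz (printed as 27, 41,
54, 68, 82). Each token lasts exactly 1/f₀ ≈ 147.06 ms, so carrier and
modulator complete whole periods per token; the modulator is cosine-phase
starting at its minimum, so every token begins and ends at zero
amplitude. Together these guarantee click-free concatenation in any
order, and they place every response frequency exactly on an FFT bin
center of the token-derived analysis windows. Tokens are grouped into
cycles, each a permutation of the five rates; a stimulus is either
random throughout ("random-random") or switches to one repeated
permutation after a transition cycle ("random-pattern"; 5! = 120 possible
patterns). Consecutive cycles never start with the previous cycle's final
token. Waveform polarity alternates between cycles so that carrier-locked
(sign-flipping) and envelope-locked (sign-invariant) neural responses can
be separated downstream.

Rendering uses a single global sample grid: token k occupies samples
`round(k·fs/f₀)` to `round((k+1)·fs/f₀)` and its phases are referenced to
its ideal onset k/f₀, so the rendered stream is the exact sampling of a
continuous waveform — concatenation adds no discontinuity at any sample
rate. Note that strict polarity alternation nulls the exact carrier line
of the *full* stimulus spectrum (energy moves to ±1/(2·cycle) sidebands);
spectral checks of the carrier therefore operate on the
polarity-corrected waveform, exactly as the carrier-locked analysis does.

**Melodic distractor.** Melodies are note/rest sequences with whole-beat
durations at 3.9 beats/s, each note a pure tone amplitude-modulated at
19.5 Hz (5 SAM periods per beat; zero-endpoint envelope, so note
boundaries are click-free). Pitches are 12-tone equal temperament. The
melody sits below a protected band — a 1/3-octave margin outside the
target's outermost AM sidebands, i.e. below (516.8−81.6)·2^(−1/3) ≈
345.4 Hz — and is duplicated three octaves (8×) higher, entirely above
598.4·2^(1/3) ≈ 753.9 Hz. Placement accounts for the ±19.5 Hz note-SAM
sidebands on both sides. The generator is a first-order random walk on
diatonic scale degrees (G2–D♯4 by default) with configurable rest
probability and duration distribution; candidate melodies are rejected
if any ≥3-note phrase occurs more than twice (repetition in the
distractor must not be confusable with repetition in the target), if no
whole-octave shift places them in the protected-band window, or — two
rules specific to the matched-noise contract below — if any note's SAM
sideband falls within 3 Hz of a different note's frequency, or if any
pitch occupies fewer than 2 beats. The paradigm's beat rate is not
prescribed anywhere; 3.9 Hz is the default because it holds an integer
number of 19.5 Hz SAM periods per beat and sits in the syllabic-rate
range where beat-locked EEG responses are expected.

**Matched noise.** The melody-matched noise shares a melody's long-term
magnitude spectrum while destroying its note sequence: one stationary
sinusoid per distinct note frequency (both registers), amplitude
proportional to the fraction of note-beats carrying that pitch, starting
phase randomized, the whole complex gated by the melody's note/rest +
19.5 Hz SAM envelope. Notes are rendered with a global-time phase
reference so repeated occurrences of a pitch add coherently — the
condition under which "amplitude ∝ beat occupancy" reproduces the
melody's line magnitudes. Two measurement caveats are inherent to this
stimulus class and drove the generator rules above: nearly coincident
lines (a sideband atop another note) make the melody's spectrum depend on
relative phase, which randomized noise phases cannot match; and a pitch
sounded only briefly yields a line too weak to measure against its
neighbors' gating skirts. Line magnitudes are compared by harmonic
regression — a joint least-squares fit of all known lines (notes ± SAM
sidebands) — which separates closely spaced lines instead of letting
them interfere; with the default generator the melody/noise line
magnitudes agree within 1 dB at every note frequency. Total *energy* is
not conserved by this construction (Σpᵢ² < 1); what is approximately
conserved, and what the tests assert, is the total spectrogram
magnitude.

## Task model

A block pairs the target with one distractor condition at a broadband-RMS
SNR (12 dB default; the "active-portion" RMS reference is available as an
option). The laboratory block holds 240 trials — 120 random-pattern, one
per pattern permutation, and 120 random-random — shuffled; the speeded
variant interleaves target-alone with distractor SNRs 18/12/6/0 dB.
Scoring: a hidden counter falls linearly from 1000 points over the
stimulus plus a 1 s response window; a response wins (correct) or
forfeits (incorrect) the remaining points, a missed response costs a flat
350. The 1 s window follows the procedure text (a figure caption says
1.5 s; both are supported, text value default). The countdown slope is
not stated beyond its endpoints; spreading 1000 points uniformly over
stimulus + window is the simplest consistent choice. Accuracy summaries
use rationalized arcsine units, θ = asin√(X/(N+1)) + asin√((X+1)/(N+1)),
RAU = (146/π)θ − 23.

## Synthetic EEG

The generator writes channels × samples (µV) containing, per trial:

* FFR — carrier-frequency sinusoid locked to cycle onsets, sign-flipped
  on negative-polarity cycles;
* EFR — during each token, a sinusoid at that token's AM rate locked to
  the token onset (polarity-invariant);
* ECFR — a base-rate sinusoid locked to token onsets whose per-token
  amplitude scales with (|ΔAM|/Δmax)^p into the token (p = 1 by default,
  matching the observed dependence of the envelope-change response on AM
  step size);
* melody-beat (3.9 Hz) and distractor-envelope (19.5 Hz) sinusoids
  locked to the trial onset, present only in distractor conditions;

each multiplied by a fixed smooth random per-channel topography gain
(mastoids carry no source signal), plus independent per-channel 1/f
noise (frequency-domain shaped, flattened below 1 Hz, scaled to 1 µV RMS
per channel by default). Components above the simulation Nyquist are
omitted with a warning, so sub-carrier analyses can run at low rates.

**Attention model.** Each trial draws an attention state
g ~ Beta(κμ, κ(1−μ)) with κ = 8; the ECFR amplitude scales by g, the
beat amplitude by (1−g), and correctness is Bernoulli with
P(correct) = logistic(−4 + 8g). Condition presets set μ and an ECFR
amplitude scale: target-alone (0.90, 1.0), matched noise (0.85, 0.65),
melody (0.65, 0.45). The anchors were chosen once so the logistic link
reproduces the reported task accuracies (≈92/91/80 %) and the ECFR
scales follow the ratio of the reported condition means
(0.070/0.048/0.030). An optional transition-locked DC ramp
(`sustained_step_uv`, default 0 — the paradigm's empirical null) lets
the sustained pipeline be validated against a known injected effect.

Everything is reproducible bit-for-bit from `SimParams.seed`.

## Analysis

**Preprocessing.** Zero-phase Butterworth band-pass 1–3000 Hz (order 4
forward-backward; the order is not prescribed by the procedure, 4 is
conventional), implemented as a low-pass followed by a high-pass: a
single band-pass whose low edge sits four orders of magnitude below
Nyquist is numerically fragile (we measured ~5 % passband error), and
the high-pass gets a reflection pad matched to its long impulse
response. Re-referencing subtracts the mastoid mean. Bad channels are
flagged by |z| > 3 on any of variance, mean absolute correlation with
the other channels, or a detrended-fluctuation Hurst exponent (≈0.5 for
white noise, ≈1 for EEG-like 1/f), and are excluded, not interpolated.

**Epochs.** Cycle windows (5/f₀ ≈ 735 ms, 1.36 Hz resolution) for the
FFR; token windows (147 ms, 6.8 Hz resolution) per AM rate for the EFRs;
two-token windows (294 ms, 3.4 Hz resolution) centered on the starts of
odd-indexed tokens — the contiguous non-overlapping tiling [t₀,t₂),
[t₂,t₄), … — for the ECFR, each labeled with the signed AM-multiple step
between its two tokens (eight classes, ±{2,4,6,8}·f₀, nominal
±14/27/41/54 Hz; a zero step cannot occur). A "last n cycles" selector
restricts to the post-transition steady state. A fourth window kind
tiles whole beat periods from the trial onset so the distractor beat and
envelope rates fall on exact bins.

**PLV.** Per channel and FFT bin, the magnitude of the mean unit phasor
across epochs; the reported spectrum is the RMS across retained
channels. Rectangular windowing is deliberate: all component frequencies
are exact bin centers by construction, so there is no leakage-phase bias
to suppress (a Hann option exists for imported data). Bins with zero
magnitude contribute zero phasors. For N noise epochs the per-channel
PLV has expectation √(π/4N), which is the noise-floor scale; the floor
at a frequency of interest is the mean PLV over ±20 bins excluding a
targeted list of stimulus-related bins (base-rate harmonics, AM rates ±
one base-rate sideband, carrier ± sidebands, beat and note-SAM rates and
low harmonics, mains). The exclusion list is intentionally not
exhaustive: at 3.4 Hz resolution an aggressive list leaves almost no
eligible bins.

**Polarity separation.** The default FFR statistic pairs consecutive
opposite-polarity cycle epochs and subtracts waveforms before the PLV:
envelope-locked activity cancels, carrier-locked activity adds. The
literal per-channel PLV(pos) − PLV(neg) is implemented as an alternative
(`mode="plv-difference"`); its expectation is ≈0 for any
polarity-symmetric response, which is why it is not the default.

**Unequal trial counts.** Because the PLV floor depends on N,
comparisons across conditions subsample every larger epoch set to the
smallest count over 600 bootstrap iterations (precomputed phasors make
this cheap) and average. The ECFR-by-ΔAM analysis groups two-token
epochs by signed step, equalizes counts, and reads the base-rate bin.
The correct/incorrect analysis computes, per participant, the asymmetry
index (C − I)/(C + I) on count-equalized PLVs, including a participant
only if at least 15 % of trials are errors and at least one category is
above the noise floor.

**Sustained response.** In order: 0.1–110 Hz zero-phase Butterworth
(order 5), downsample to 256 Hz, average reference over scalp channels,
1 s prestimulus baseline, single-pass rejection of trials whose mean
power exceeds the across-trial mean by 2 SD (upper tail only), 30 Hz
low-pass, denoising source separation biased toward trial-reproducible
activity (whiten by total covariance at relative rank tolerance 1e-9,
rank whitened directions by the covariance of the trial average, keep 5
components), RMS across channels of the trial average. The pattern
statistic is the mean over cycles +2..+4 after the transition minus the
mean over the two cycles before it; its floor is the distribution of the
same statistic at 1000 uniformly drawn fake transition points (the
iteration count is not prescribed). Note that a DC step is outside the
0.1–110 Hz band: validation against an injected step therefore compares
the pipeline against the known source waveform passed through the same
filter chain, not against the raw step height.

## Problem sizes

The generator's structural defaults mirror the full recording setup (64
scalp channels + 2 mastoids at 16384 Hz, 12-cycle trials, 240-trial
blocks). The test suite and acceptance script run the same pipeline at
desk scale — 8–16 channels, 510–512 Hz (3400 Hz when the carrier is
needed; 3400 = 500 samples per token makes the event grid rounding-free),
16–40 trials per participant, cohorts of 6–20 — chosen so the full suite
completes in a few minutes while every statistical contrast it asserts
is still comfortably powered. The cohort drivers in `multisync.cohort`
expose these sizes as parameters.

## What the synthetic experiments show — and don't

Passing tests demonstrate that the analysis chain recovers what the
generator puts in: PLV floors at their theoretical value, monotone PLV
in locking amplitude, polarity separation, ΔAM scaling, the
correct/incorrect asymmetry signs (positive for the target's
envelope-change response, negative for the distractor beat, null for
attention-invariant EFRs), and the distraction-level ordering of the
envelope-change response. They cannot validate the generative
assumptions themselves against biology: real EEG has non-stationary,
spatially correlated noise, artifacts, latency jitter, imperfect phase
locking, and head-volume conduction, none of which the
topography-gain-times-sinusoid model attempts. The simulator is a test
harness for the measurement machinery and a ground-truth generator for
power exploration, not a forward model of the auditory pathway.

## Known limitations

* The melody generator is a rule-based stand-in for a learned melody
  model; it shares the constraints (register, protected band, phrase
  filter, beat/SAM commensurability) but not the musical statistics.
* SNR mixing defines level by broadband RMS over the full stimulus;
  absolute calibration (dB SPL) and transducer compensation are out of
  scope.
* Bad-channel detection implements the variance/correlation/Hurst
  triplet on a single fixed threshold (3 SD); no interpolation.
* The sustained-response DSS assumes enough trials for a stable total
  covariance; with rank-deficient (noise-free synthetic) data it keeps
  the available rank and warns.
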