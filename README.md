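# multisync

Stimulus design, task simulation and EEG analysis for a multiplexed
auditory-synchronization paradigm: one target sound stream carries
nested temporal features spanning three orders of magnitude — temporal
fine structure (a 516.8 Hz carrier), five amplitude-modulation rates
(27–82 Hz), a regular envelope-change rate (6.8 Hz) and a slow
random-vs-repeating arrangement (~0.5 Hz) — while a melodic distractor
or its spectrally matched noise occupies protected frequency bands on
either side. Phase-locking analysis of the EEG then reads out neural
synchronization to every target and distractor feature simultaneously:
the frequency-following response (FFR) to the carrier, envelope-following
responses (EFRs) at the AM rates, the envelope-change following response
(ECFR) at the token rate, and beat/envelope responses to the distractor.

The package is aimed at auditory-neuroscience researchers who want to
(a) generate the stimuli and trial structure of such a paradigm,
(b) analyze multichannel EEG recorded with it, or (c) validate the
analysis chain end-to-end on synthetic recordings with known ground
truth — including the attention-dependent trade-off between target and
distractor synchronization on correct versus incorrect trials.

## The measurements at its core

For epochs matched to each timescale (one stimulus cycle for the FFR,
one SAM token for the EFRs, two tokens for the ECFR), the phase-locking
value at channel c and frequency bin f is

    PLV_c(f) = | (1/N) Σ_n exp(i·φ_{n,c}(f)) |

(the resultant of the FFT phases across N epochs), aggregated as the RMS
across channels. Pure noise gives PLV ≈ √(π/4N), so unequal trial counts
are equalized by bootstrap subsampling (600 iterations) before any
comparison. Carrier-locked activity flips sign with stimulus polarity
while envelope-locked activity does not, so the FFR statistic subtracts
paired opposite-polarity epochs before the PLV. Synchronization
differences between correct and incorrect trials are expressed as an
asymmetry index AI = (C − I)/(C + I). A separate slow pipeline
(0.1–110 Hz, denoising source separation, RMS trial average) quantifies
the sustained pattern-recognition potential and its bootstrap floor.

## Worked example

Simulate one participant's melody-distractor block (40 trials, 16
channels, desk-scale sampling) and measure target and distractor
synchronization split by response accuracy:

```python
import multisync as ms

result = ms.run_participant(seed=42, condition="target+melody",
                            n_trials=40)
for k in ("error_rate", "ecfr_plv", "ecfr_floor", "ecfr_ai",
          "beat_plv", "beat_floor", "beat_ai"):
    print(f"{k:12s} {result[k]:+.3f}")
```

prints

```
error_rate   +0.250
ecfr_plv     +0.068
ecfr_floor   +0.027
ecfr_ai      +0.032
beat_plv     +0.108
beat_floor   +0.038
beat_ai      +0.036
```

The participant erred on 25 % of trials; the target's envelope-change
response (0.068) and the distractor's beat response (0.108) both sit
well above their noise floors. Single-participant asymmetry indices are
noisy — the direction of the attention trade-off emerges at the group
level:

```python
df = ms.cohort_asymmetry(n_participants=12, seed=5, n_trials=40)
inc = df[df.included]
print(inc[["ecfr_ai", "beat_ai", "efr_68_ai"]].mean().round(3))
```

```
ecfr_ai      0.082
beat_ai     -0.168
efr_68_ai    0.008
```

— synchronization to the target's envelope changes is *higher* on
correct trials (positive AI), synchronization to the distractor's beat
is higher on *incorrect* trials (negative AI), and the
attention-invariant 68 Hz EFR shows no asymmetry. Stimuli themselves are
available from the same API (`build_target`, `render_melody`,
`make_matched_noise`, `mix_at_snr`) or from the `multisync` command line
(`multisync stimulus target --seed 1 --cycles 12 --out target.wav`).

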