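# rhythmtag

Frequency-tagging EEG pipeline for measuring **cortical tracking of speech
rhythm** at the three rates carried by rhythmically neutral CVn-syllable
speech: the foot (2.5 Hz), the syllable (5 Hz) and the mora (10 Hz).  It
is written for auditory/EEG researchers who want the complete
stimulus-to-statistics procedure as tested, seed-reproducible code —
including synthetic stimulus and EEG generators, so every stage can be
verified end-to-end against known ground truth without human data.

## What it computes

Stimuli are 30 s sequences of 150 concatenated 200 ms
consonant–vowel–nasal syllables (14-token inventory, constrained shuffle
with no immediate repeats, 180 Hz fundamental; 280 Hz pitch deviants for
the behavioural task; a 1-channel noise-vocoded non-speech control).  The
stimulus envelope e(t) = |analytic(x)(t)| predicts where responses can
occur: its spectrum peaks at 5 Hz, weakly at 10 Hz, and not at 2.5 Hz.

EEG (128 channels + Cz reference, 1000 Hz) is band-passed 0.3–30 Hz
(zero-phase windowed-sinc FIR), epoched 0–30 s, cleaned (robust
bad-channel replacement, ocular template regression, rejection of epochs
exceeding ±100 µV, ≥6 of 8 epochs required), average-referenced and
averaged per condition.  The average is zero-padded to 40 s giving an
amplitude spectrum A(f) with Δf = 0.025 Hz.  Two local noise corrections:

* corrected amplitude:  A*(f) = A(f) − mean{ A(f ± kΔf) : k = 2..12 }
* significance:  z(f) = [A(f) − mean(N)] / sd(N), with N the 20
  neighbouring bins (10 per side, adjacent bin excluded); z > 3.1
  (one-tailed p < 0.001) marks a tracked response.

Response magnitude = mean A*(f) over a 10-electrode fronto-central ROI.
Group inference uses linear mixed-effects models with simple-coded
factors, standardized amplitude, random intercepts per participant and
Satterthwaite degrees of freedom (validated against lme4/lmerTest):

```
Amplitude ~ Frequency + Group + Frequency:Group            + (1 | Participant)   # cross-language
Amplitude ~ Frequency * Group * Stimulus                   + (1 | Participant)   # speech vs non-speech
Amplitude10 ~ Group + Amplitude5                           + (1 | Participant)   # harmonic check
```

## Worked example

```python
import numpy as np
from rhythmtag import stimgen, envspec
from rhythmtag.eegsim import SimConfig, simulate_participant
from rhythmtag.preprocess import preprocess_recording
from rhythmtag.freqtag import analyze_evoked

# a stimulus and its envelope spectrum
inv   = stimgen.build_inventory()
plan  = stimgen.plan_sequence(inv, seed=1)
audio = stimgen.render_sequence(plan, inv, stimgen.voice_params("english"))
spec  = envspec.envelope_spectrum(envspec.hilbert_envelope(audio), 16000)
print("envelope 5 Hz: %.3f   10 Hz: %.3f" % (
    envspec.amplitude_at(spec, 5.0), envspec.amplitude_at(spec, 10.0)))

# one simulated participant through the full pipeline
recs, truth = simulate_participant(SimConfig(), "french", 2001, "fr01",
                                   conditions=["french"])
evoked, log = preprocess_recording(recs["french"])
res = analyze_evoked(evoked)
print("embedded 5 Hz: %.3f uV   estimated: %.3f uV   z = %.1f" % (
    truth.bin_amplitudes[("french", 5.0)], res["roi"][5.0], res["z"][5.0]))
```

Output:

```
envelope 5 Hz: 0.117   10 Hz: 0.056
embedded 5 Hz: 0.653 uV   estimated: 0.507 uV   z = 17.4
```

The envelope line is the acoustic model of response: the syllable rate
dominates the mora rate and there is no foot-rate energy to track.  The
EEG line shows the pipeline recovering an embedded 5 Hz response well
above the z > 3.1 significance cut; the estimate sits slightly below the
embedded value because neighbour-bin subtraction removes the local noise
floor (and ~5% of the peak's own spectral leakage) — recovery is assessed
by correlation across participants, which exceeds r = 0.98 at default
noise.

A full simulated replica (stimuli → cohort → preprocessing → spectra →
models, with a report, tidy CSVs and the resolved configuration) runs
from the shell:

```bash
rhythmtag run --out results/demo        # or: rhythmtag run --config my.yaml --out ...
rhythmtag stimgen --voice french --n-sequences 8 --seed 1 --out stim/
rhythmtag envspec stim/french_seq00.wav --out spectrum.csv
rhythmtag stats --model 1 results/demo/roi_responses.csv
```

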