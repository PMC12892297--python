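# bimodalffr

Analysis pipeline for **frequency-following responses (FFRs) to simulated
bimodal hearing** — a cochlear-implant simulation (noise vocoder) in one ear
plus lowpass-filtered acoustic speech in the other. The package asks three
questions about scalp-recorded FFRs evoked by steady-state vowels:

1. How does neural encoding of the fundamental (f0) and first formant (F1)
   grow as the acoustic ear's bandwidth widens?
2. Can vowel identity be decoded objectively from FFR spectra, and does
   decoding improve with bandwidth?
3. Does *neural* bimodal benefit predict *perceptual* (speech-in-noise)
   bimodal benefit across listeners?

It is aimed at auditory-neurophysiology researchers who want a tested,
end-to-end reference implementation of this analysis chain. No human
recordings ship with it: a first-class synthetic-data module generates
continuous EEG with planted phase-locked structure, so every stage is
verifiable against ground truth.

## The measurements

**Stimuli.** Three source–filter vowels (/ε/, /i/, /ʊ/; f0 = 130 Hz,
F1 = 520/260/390 Hz, ~390 ms) are processed into five conditions:
`Voc` (8-channel white-noise vocoder alone, channels spaced by the
Greenwood map F(x) = A(10^{ax} − k) over 200–7000 Hz, envelope cutoff
400 Hz at 24 dB/oct) and `Voc+125/250/500/750` (vocoder right ear +
8th-order Butterworth lowpass left ear, envelope-aligned by
cross-correlation).

**FFR spectra.** Continuous EEG (10 kHz) is bandpassed 70–1000 Hz,
epoched −50…500 ms, detrended, rejected at ±70 μV, baseline-corrected.
The 150–250 ms steady state of the polarity-A average is Fourier
transformed into a 250-point, 0–1000 Hz amplitude spectrum (4 Hz bins),
from which f0 and F1 component amplitudes are read.

**PLV spectra.** Each single trial is short-time Fourier transformed
(60 ms windows, 1 ms hop, zero-padded to 1 Hz bins); per-bin unit phasors
are averaged over the N trials:

    PLV(t, f) = | (1/N) Σₙ exp(i·φₙ(t, f)) |  ∈ [0, 1]

time-averaged over 150–250 ms, polarity-averaged, and compared against a
prestimulus (−50–0 ms) noise floor. Neural bimodal benefit is the
across-vowel mean ΔPLV (Voc+750 − Voc) at f0 and at each vowel's F1.

**Decoding.** Per condition, the 250-bin spectra (one per subject per
vowel) are standardized, reduced to 5 principal components (fit on
training folds only), and classified by a one-against-one linear SVM
(3 binary classifiers), cross-validated subject-wise in 3 folds iterated
1000 times, against a label-shuffled null; significance uses
p = (a+1)/(n+1) with a = #{null > median(reference)}.

**Benefit model.** SNR-50 speech-in-noise thresholds come from
Spearman–Kärber scoring of key-words-correct over a +21→0 dB ladder
(3 dB steps, two list pairs averaged). Perceptual benefit
(threshold(Voc) − threshold(Voc+750)) is regressed on Fisher-z
transformed neural benefits at f0 and F1 by OLS, with variance inflation
factors as the collinearity diagnostic.

## Worked example

```python
from bimodalffr import pipeline
res = pipeline.run_pipeline(pipeline.demo_config(seed=1))  # ~7 min, 1 CPU

f1 = res.amplitudes[res.amplitudes.component == "F1"]
print(f1.groupby(["condition", "vowel"]).amplitude_uv.mean().unstack().round(4))
```

prints the cohort-mean F1 spectral amplitude (μV) per condition:

```
vowel           i       ʊ       ε
condition
Voc        0.0615  0.0197  0.0060
Voc+125    0.0726  0.0277  0.0084
Voc+250    0.1024  0.0389  0.0097
Voc+500    0.1416  0.0792  0.0349
Voc+750    0.1628  0.0936  0.0583
```

— F1 encoding grows monotonically with acoustic bandwidth for every
vowel, the central physiological effect. The same run gives median
decoding accuracies of 0.44/0.50/0.56/0.89/0.78 across the five
conditions (all significant against the permutation null; adjacent
conditions overlap, as in real data) and a mean perceptual benefit of
≈ +4.9 dB. The numbered scripts under `analysis/`
narrate the same workflow stage by stage (stimuli → example subject →
demo cohort → decoding summary → benefit regression) and write their
tables under `results/`.

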