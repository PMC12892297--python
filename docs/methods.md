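# Methods

This note documents the models implemented in `bimodalffr`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a reader would otherwise have to
reverse-engineer from the code.

## Stimulus synthesis

Vowel tokens are synthesized, not recorded: a harmonic source with 1/k
amplitude rolloff and **phase-aligned (cosine) harmonics** — the
glottal-pulse-like alignment that gives speech its f0-rate temporal
envelope — is shaped by a second-order resonator at F1 (60 Hz bandwidth)
plus a fixed resonator at 1.5 kHz (150 Hz bandwidth) for naturalism, with
5 ms raised-cosine ramps. Only f0 (130 Hz), F1 (520/260/390 Hz) and
duration (390 ms) are controlled; consonant flanks are omitted because
every downstream analysis uses the 150–250 ms steady state. Since each
F1 here is an exact f0 harmonic, the resonator makes that harmonic
dominant, and the measured F1 (smoothed-spectral-envelope peak below
1 kHz, 40 Hz Gaussian smoothing) lands exactly on the nominal value.

The vocoder uses the standard human Greenwood map constants (A = 165.4,
a = 2.1 per unit position, k = 0.88) to spread 8 channels over
200–7000 Hz. Per channel: 4th-order Butterworth analysis bandpass,
half-wave rectification + 4th-order 400 Hz lowpass for the envelope
(24 dB/oct ⇒ order 4; a Hilbert-envelope mode is available), envelope ×
same-band-filtered white noise, channels re-filtered after modulation
(the conservative choice; it keeps modulation sidebands in band), summed
and RMS-matched to the input. Stimulus-branch filters run causally
(stimulus processing is real-time-like); analysis filters elsewhere are
zero-phase. Sound level is relative in a digital pipeline: the 80 dB SPL
presentation level maps to a reference RMS (0.05 full scale), and the
lowpass branch keeps the gain at which the *unfiltered* token sits at
reference level, so narrow cutoffs genuinely carry less energy.

Envelope alignment maximizes the normalized cross-correlation of the two
ears' smoothed rectified envelopes over ±20 ms (unnormalized correlation
is biased by overlap length on near-flat envelopes; measured vocoder
group delays are ~5 ms, well inside the window).

A caveat discovered while validating: for /i/ (F1 = 260 Hz) the vocoded
temporal envelope is *dominated* by 260 Hz rather than f0 — the lowest
channel contains essentially one strong harmonic — and intrinsic
noise-carrier envelope fluctuations crowd 70–120 Hz. The f0 periodicity
therefore survives as a clear spectral *line* (≥ 4× the 70–1000 Hz
band median for all three vowels) but is the global envelope-spectrum
maximum only for /ε/. The tests assert exactly that.

## Synthetic FFR cohorts

The generator is a statistical emulator, not a brainstem model: each
trial's response is a sum of sinusoids at f0, 2f0, 3f0 (envelope
components, phase invariant to stimulus polarity) and the vowel's F1
(temporal-fine-structure component, phase flips by π for polarity B),
delayed by a fixed 8 ms latency, with per-trial von Mises phase jitter
of concentration κ. Expected PLV is therefore the Bessel ratio
I₁(κ)/I₀(κ), which is what parameter-recovery tests check. Component
mean phases share one subject-level reference phase plus a fixed 3 ms
internal delay so components that coincide in frequency (e.g. /i/'s F1
at 260 Hz and the 2f0 envelope harmonic) superpose coherently instead of
cancelling at random. Envelope amplitude profiles are vowel-specific
(/i/ envelope dominated by 260 Hz, weak f0 — the structure that makes
vocoder-only vowels partially decodable).

Condition structure (the "study conditions"): f0 gain grows 12% per
bandwidth step; F1 gain follows a weight
w = 0.2·(cutoff/750) + 0.8·σ((cutoff − F1)/75 Hz), zero without an
acoustic ear — monotone in cutoff with a steep rise once the cutoff
passes the vowel's F1. Subject κ multipliers are lognormal (sd 0.35)
around κ_f0 = 2.0 and κ_f1 = 1.5, driven by a shared latent factor
(r = 0.9) so f0 and F1 benefits covary across subjects. Background EEG
is 1/f-shaped Gaussian noise (2 μV RMS single-trial, chosen so planted
PLVs at defaults sit well above the prestimulus floor at the trial
counts used); responses are ~0.1 μV — both in the range of real FFR
recordings. Artifacts (default 2% of trials) are 90–155 μV bursts with
90–300 Hz oscillatory content, so they survive the 70–1000 Hz analysis
bandpass and deterministically trip the ±70 μV rejection. Trials are
laid out serially, alternating polarity, with 620–680 ms jittered onset
intervals.

Behavior: per condition, a subject's true SNR-50 generates binomial
key-word counts (4 words per SNR step, logistic slope 2 dB ≈ 12.5%/dB)
over the +21→0 dB ladder, twice (two list pairs). Mean bimodal benefit
is 5 dB with 3 dB between-subject spread, typical of vocoder+acoustic
simulations. The neural→perceptual link is planted so the population R²
between true neural benefit and the *measured* perceptual benefit equals
the configured value (default 0.35): the latent noise is sized after
subtracting the analytic Spearman–Kärber scoring variance
(step²·Σp(1−p)/words ≈ 1.5 dB²) and orthogonalized against the realized
predictor, making the planting exact for each cohort design. A config
with a noise budget smaller than the scoring variance raises.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: nonstationary latency and amplitude drift,
condition-randomized block ordering effects, cochlear/brainstem
nonlinearities (the response is a fixed small set of sinusoids),
electrode impedance drift, non-Gaussian artifact families, or any
electrical stimulus artifact of real cochlear implants.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band edges at 70 and
1000 Hz; epochs are the half-open window [−50, 500) ms — exactly 5500
samples at 10 kHz, uniform lengths, no double counting. Cleaning order
is detrend (least-squares line over the whole epoch) → reject (any
|sample| > 70 μV) → baseline (subtract the −50–0 ms mean); the order is
exposed in code and the rejection is required by test to match a
brute-force amplitude scan exactly. Cleaning is idempotent.

## Spectra

The 100 ms steady-state segment is zero-padded to 2500 samples so the
FFT grid has 4 Hz bins; the single-sided amplitude spectrum is truncated
to 250 points (0–996 Hz). Scaling is defined by a calibration contract:
an on-bin sinusoid of amplitude a μV fully inside the window reports a
(the exact normalization used in the original analyses is unknowable, so
the contract replaces it). No taper by default (steady-state segment;
Hann available). Component targets not on the 4 Hz grid (130, 390 Hz)
use the nearest bin with ties broken toward the lower bin (130 → 128);
a ±1-bin local-max option exists. Zero-padding redistributes power, so
Parseval holds with the known factor nfft/nseg = 2.5 (tested).

## PLV

Only full 600-sample windows are used; the time grid is the window
*centers* (a 550 ms epoch gives 491 windows at a 1 ms hop, centers −20
to 470 ms). Each window is zero-padded to 10 000 samples for 1 Hz
(interpolated) bins. The across-trial resultant is normalized by the
trial count N — required for the stated [0, 1] range — and zero-magnitude
bins contribute a zero vector without reducing N (conservative).
Polarity averaging averages the two PLV spectra, not complex vectors.
Only retained (artifact-free) trials enter. The noise floor uses a
single 60 ms window anchored at 0 ms with the missing 10 ms zero-padded;
for PLV this is numerically identical to analyzing the native 50 ms
window, because zero-padding multiplies every trial's spectrum by the
same linear phase factor, which cancels in the resultant — so no
alternative mode is provided.

## Decoding

Standardization and PCA are fit on the training folds only — fitting on
all data leaks the held-out subjects' spectra into the features; a
compatibility switch is deliberately *not* provided because the leaky
variant has no use beyond replicating an ambiguity. SVM: linear kernel,
C = 1.0, one-against-one with majority vote and margin-based tie-break.
Folds partition subjects (6 per fold at n = 18); an in-loop audit
asserts train/test subject disjointness. The null permutes labels across
observations anew each iteration, with fresh fold assignments.

Two statistical properties of the prescribed significance recipe are
worth knowing. First, p = (a+1)/(n+1) counts null values above the
*median* of the reference distribution, so under exchangeability it
estimates P(null > median) and concentrates at 0.5 — it is not a
uniformly distributed p-value, and the tests assert the attainable
property (≈ 0.5 for exchangeable continuous inputs, rarely significant
for exchangeable procedures). Second, at 18 observations the
across-observation label permutation is biased *below* chance (≈ 0.22
vs 1/3): sampling without replacement anticorrelates training and
held-out class frequencies. True-vs-null comparisons are therefore
somewhat anticonservative; this is a property of the published
procedure, retained verbatim here.

## Benefit model

Spearman–Kärber: SNR-50 = top + step/2 − step·(total correct)/(words per
step); all-correct gives −1.5 dB, none-correct +22.5 dB; list pairs are
averaged. The commercial normative "SNR loss" correction is a
configurable constant subtraction (the normative formula is proprietary).
Fisher z is applied to the ΔPLV benefit values themselves (applying it
to raw PLVs before differencing is available via config). OLS with
intercept; R², adjusted R², overall F, per-predictor t, and
VIF_j = 1/(1 − R²_j). Recovery of a planted population R² is measured
with **adjusted** R² — the standard estimator of population R²; raw R²
at n = 18 with two predictors is upward-biased by ≈ p(1−ρ²)/(n−1) ≈ 0.08
and cannot be an unbiased recovery metric.

## Problem sizes

The demonstration cohort is 6 subjects × 3 vowels × 5 conditions ×
200 trials per polarity — sized so an end-to-end run, including PLV for
the vocoder-only and widest-bandwidth conditions, completes in a few
minutes on one CPU while leaving every directional effect (F1 growth,
decoding improvement, positive perceptual benefit) clearly resolved.
Estimator characterization for the benefit regression uses 200 simulated
18-subject cohorts at profile level (true neural benefits + scored
behavior), where EEG simulation adds nothing: at full 2000-trial
recording counts the neural measurement error is negligible relative to
behavioral scoring noise. Classifier distributions use 200 iterations where
the shape, not the tail resolution, is under test.

## Known limitations

- The response emulator has no harmonics above 3f0 and no spectral
  splatter between bins; real FFRs contain both.
- PLV growth with bandwidth is planted directly (κ and amplitude
  weights); the pipeline demonstrates *recovery*, not emergence from
  acoustics.
- The one-against-one vote implements majority-with-margin-tie-break;
  the original description of combining pairwise classifiers is ambiguous
  and other readings are defensible.
- Condition-vs-condition significance reports the larger of the two
  directional empirical probabilities, a conservative symmetric choice.
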