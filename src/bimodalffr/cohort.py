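"""Synthetic FFR cohorts: continuous EEG with planted phase-locked responses.

The generator emulates the statistical structure the downstream analyses
assume, not brainstem biophysics: each trial's response is a small set of
sinusoids at f0 (130 Hz), its harmonics, and the vowel's F1, with per-trial
phases drawn von Mises around a polarity-dependent mean.  Temporal-fine-
structure (F1) components flip phase when the stimulus polarity is
inverted; envelope (f0-harmonic) components do not — the physical basis
for (A+B)/2 averaging emphasizing the envelope and (A-B)/2 the TFS.
Trials ride on 1/f-shaped Gaussian background EEG with occasional
high-amplitude artifacts.  Each subject also carries a true speech-in-noise
threshold per condition whose bimodal benefit is linearly linked to the
subject's true neural (PLV) benefit, with noise calibrated so the planted
population R² between neural and perceptual benefit is exact for the
realized cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.special import expit

from .stimuli import (
    CONDITIONS,
    CONDITION_CUTOFFS,
    DEFAULT_VOWELS,
    BimodalStimulus,
    VowelSpec,
)

__all__ = [
    "Event",
    "ContinuousEEG",
    "BehavioralRun",
    "SubjectProfile",
    "CohortConfig",
    "make_cohort",
    "simulate_trials",
    "simulate_behavior",
    "expected_plv",
    "condition_f0_gain",
    "condition_f1_weight",
    "SNR_STEPS",
]

EEG_RATE = 10_000.0
#: BKB-SIN-style SNR ladder: +21 dB down to 0 dB in 3 dB steps.
SNR_STEPS = np.arange(21.0, -0.1, -3.0)

#: Per-vowel relative amplitudes of the envelope components at f0, 2f0, 3f0.
#: Vowel envelopes are idiosyncratic: /i/ (F1 = 260 Hz = 2·f0) has an
#: envelope dominated by 260 Hz rather than f0.
ENVELOPE_PROFILES = {
    "ε": (1.0, 0.25, 0.15),
    "i": (0.35, 1.0, 0.10),
    "ʊ": (0.9, 0.30, 0.45),
}


def expected_plv(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution: I1(κ)/I0(κ)."""
    if np.isinf(kappa):
        return 1.0
    if kappa == 0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def condition_f0_gain(condition: str) -> float:
    """Growth of f0 (envelope) encoding with acoustic bandwidth.

    Adding lowpass acoustic energy contributes resolved harmonics that
    modestly bolster f0 encoding; 12% per condition step.
    """
    idx = CONDITIONS.index(condition)
    return 1.0 + 0.12 * idx


def condition_f1_weight(condition: str, f1: float) -> float:
    """F1 (TFS) encoding weight in [0, 1] for a condition and vowel F1.

    Zero acoustic ear -> 0.  With acoustic input the weight grows with
    cutoff and rises steeply once the lowpass cutoff passes the vowel's F1
    (the point at which the acoustic ear actually delivers the formant).
    """
    cutoff = CONDITION_CUTOFFS[condition]
    if cutoff is None:
        return 0.0
    return float(0.2 * cutoff / 750.0 + 0.8 / (1.0 + np.exp(-(cutoff - f1) / 75.0)))


@dataclass(frozen=True)
class Event:
    sample: int
    stimulus: str  # e.g. "i|Voc+750"
    polarity: str  # "A" or "B"


@dataclass
class ContinuousEEG:
    """Single-channel continuous recording (μV) with stimulus-onset events."""

    samples: np.ndarray
    rate: float = EEG_RATE
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if any(
            self.events[i].sample > self.events[i + 1].sample
            for i in range(len(self.events) - 1)
        ):
            raise ValueError("events must be sorted by sample index")


@dataclass(frozen=True)
class BehavioralRun:
    """Key-words-correct per SNR step for the two list pairs of one list."""

    condition: str
    snr_db: np.ndarray
    correct: np.ndarray  # shape (2, n_steps)
    words_per_step: int

    def __post_init__(self):
        if self.correct.shape != (2, len(self.snr_db)):
            raise ValueError("expected counts for two list pairs")
        if np.any(self.correct < 0) or np.any(self.correct > self.words_per_step):
            raise ValueError("correct counts out of range")


@dataclass
class SubjectProfile:
    """Generating parameters for one synthetic subject."""

    subject_id: int
    plv_gain_f0: dict[str, float]  # condition -> κ at f0
    plv_gain_f1: dict[tuple[str, str], float]  # (condition, vowel) -> κ at F1
    response_amp: float  # μV scale of planted components
    latency_ms: float
    noise_level: float  # μV RMS of 1/f background
    artifact_rate: float
    true_snr50: dict[str, float]  # condition -> true SNR-50 (dB)
    psychometric_slope: float
    seed: int

    def __post_init__(self):
        if not (0.0 <= self.artifact_rate <= 0.1):
            raise ValueError("artifact_rate outside [0, 0.1]")
        for v in self.plv_gain_f0.values():
            if v < 0:
                raise ValueError("κ must be nonnegative")

    def true_neural_benefit(self, vowels=DEFAULT_VOWELS) -> tuple[float, float]:
        """Noise-free (f0, F1) PLV benefit: Voc+750 minus Voc, vowel-averaged."""
        f0b = expected_plv(self.plv_gain_f0["Voc+750"]) - expected_plv(
            self.plv_gain_f0["Voc"]
        )
        f1b = float(
            np.mean(
                [
                    expected_plv(self.plv_gain_f1[("Voc+750", v.label)])
                    - expected_plv(self.plv_gain_f1[("Voc", v.label)])
                    for v in vowels
                ]
            )
        )
        return f0b, f1b


@dataclass(frozen=True)
class CohortConfig:
    """Population-level generator settings (defaults = study conditions)."""

    kappa_f0_base: float = 2.0
    kappa_f1_base: float = 1.5
    kappa_f1_floor: float = 0.25  # vocoder alone transmits some F1 via envelope
    kappa_f1_span: float = 2.75
    subject_sd: float = 0.35  # lognormal sd of subject κ multipliers
    neural_latent_corr: float = 0.9  # shared latent behind f0 and F1 gains
    response_amp: float = 0.10  # μV
    latency_ms: float = 8.0
    noise_level: float = 2.0  # μV RMS
    artifact_rate: float = 0.02
    planted_r2: float = 0.35  # population R², neural -> measured perceptual benefit
    mean_benefit_db: float = 5.0
    benefit_sd_db: float = 3.0
    snr50_voc_mean: float = 13.0
    snr50_voc_sd: float = 1.5
    psychometric_slope: float = 2.0  # dB
    words_per_step: int = 4
    condition_benefit_fraction: tuple[float, ...] = (0.0, 0.35, 0.55, 0.8, 1.0)

    def scoring_variance(self) -> float:
        """Analytic Spearman-Kärber variance (dB²) of a measured *benefit*.

        Each threshold averages two list pairs and the benefit differences
        two thresholds, so var(benefit) = var(single list pair) =
        step² Σ p(1-p) / words for the logistic psychometric function.
        """
        p = 1.0 / (1.0 + np.exp(-(SNR_STEPS - self.snr50_voc_mean) / self.psychometric_slope))
        return float(9.0 * np.sum(p * (1 - p)) / self.words_per_step)


def make_cohort(
    n_subjects: int = 18,
    seed: int = 0,
    config: CohortConfig = CohortConfig(),
    conditions: tuple[str, ...] = CONDITIONS,
    vowels: tuple[VowelSpec, ...] = DEFAULT_VOWELS,
) -> list[SubjectProfile]:
    """Draw a reproducible cohort of subject profiles.

    F1 phase-locking gain is nondecreasing in acoustic bandwidth for every
    subject by construction, and each subject's perceptual bimodal benefit
    is a linear function of their true neural benefit plus noise whose
    variance is set so the population R² equals ``config.planted_r2``
    exactly for the realized cohort predictors.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    c = config
    rho = c.neural_latent_corr
    profiles: list[SubjectProfile] = []
    for sid in range(n_subjects):
        u = rng.standard_normal()
        e0, e1 = rng.standard_normal(2)
        m0 = np.exp(c.subject_sd * (rho * u + np.sqrt(1 - rho**2) * e0))
        m1 = np.exp(c.subject_sd * (rho * u + np.sqrt(1 - rho**2) * e1))
        gain_f0 = {
            cond: c.kappa_f0_base * m0 * condition_f0_gain(cond) for cond in conditions
        }
        gain_f1 = {
            (cond, v.label): c.kappa_f1_base
            * m1
            * (c.kappa_f1_floor + c.kappa_f1_span * condition_f1_weight(cond, v.f1))
            for cond in conditions
            for v in vowels
        }
        profiles.append(
            SubjectProfile(
                subject_id=sid,
                plv_gain_f0=gain_f0,
                plv_gain_f1=gain_f1,
                response_amp=c.response_amp * np.exp(0.2 * rng.standard_normal()),
                latency_ms=c.latency_ms,
                noise_level=c.noise_level * np.exp(0.1 * rng.standard_normal()),
                artifact_rate=c.artifact_rate,
                true_snr50={},
                psychometric_slope=c.psychometric_slope,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )

    # Plant the neural -> perceptual link on the realized cohort.
    z = np.array(
        [np.arctanh(np.clip(p.true_neural_benefit(vowels), -0.999, 0.999)) for p in profiles]
    )
    combined = z.sum(axis=1)
    combined = (combined - combined.mean()) / max(combined.std(), 1e-12)
    signal_sd = c.benefit_sd_db * np.sqrt(c.planted_r2)
    # The planted R² targets the *measured* benefit, so the binomial scoring
    # noise added later by snr50() counts against the noise budget.
    noise_var = c.benefit_sd_db**2 * (1.0 - c.planted_r2) - c.scoring_variance()
    if noise_var < 0:
        raise ValueError(
            "scoring noise alone exceeds the noise budget implied by "
            "planted_r2/benefit_sd_db; raise words_per_step or benefit_sd_db"
        )
    noise_sd = np.sqrt(noise_var)
    noise = rng.standard_normal(n_subjects)
    noise = (noise - noise.mean()) / max(noise.std(), 1e-12)
    # orthogonalize the noise against the predictor so the planted R² is exact
    noise = noise - combined * float(np.dot(noise, combined) / np.dot(combined, combined))
    noise = noise / max(noise.std(), 1e-12)
    benefit = c.mean_benefit_db + signal_sd * combined + noise_sd * noise
    frac = dict(zip(CONDITIONS, c.condition_benefit_fraction))
    for p, b in zip(profiles, benefit):
        base = c.snr50_voc_mean + c.snr50_voc_sd * rng.standard_normal()
        p.true_snr50 = {cond: base - b * frac.get(cond, 1.0) for cond in conditions}
    return profiles


# ---------------------------------------------------------------------------
# Trial-level EEG synthesis

_EPOCH_PRE_S = 0.050
_EPOCH_POST_S = 0.500


def _pink_noise(n: int, rate: float, rms: float, rng, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with 1/f^exponent power shaping, scaled to target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x * (rms / np.sqrt(np.mean(x**2)))


def _stimulus_params(stimulus: BimodalStimulus):
    v = stimulus.vowel
    prof = ENVELOPE_PROFILES.get(v.label, (1.0, 0.3, 0.2))
    freqs = [v.f0, 2 * v.f0, 3 * v.f0, v.f1]
    flips = [False, False, False, True]
    return v, prof, freqs, flips


def simulate_trials(
    stimulus: BimodalStimulus,
    profile: SubjectProfile,
    n_per_polarity: int = 1000,
    *,
    rate: float = EEG_RATE,
    isi_s: tuple[float, float] = (0.62, 0.68),
    artifact_threshold: float = 70.0,
    noise_exponent: float = 1.0,
) -> ContinuousEEG:
    """Continuous EEG containing ``2 × n_per_polarity`` alternating-polarity trials.

    Each trial's response is the sum of envelope sinusoids at f0, 2f0, 3f0
    (polarity-invariant) and a TFS sinusoid at the vowel's F1 (phase flips
    by π for polarity "B"), delayed by the subject's latency, with per-trial
    von Mises phase jitter of concentration κ taken from the profile.
    Deterministic given (stimulus, profile, n_per_polarity).
    """
    if n_per_polarity < 1:
        raise ValueError("need at least one trial per polarity")
    v, prof, freqs, flips = _stimulus_params(stimulus)
    cond = stimulus.condition
    cond_idx = CONDITIONS.index(cond)
    vowel_idx = {"ε": 0, "i": 1, "ʊ": 2}.get(v.label, 3)
    rng = np.random.default_rng([profile.seed, cond_idx, vowel_idx, 17])

    g0 = condition_f0_gain(cond)
    w1 = condition_f1_weight(cond, v.f1)
    amps = [
        profile.response_amp * prof[0] * g0,
        profile.response_amp * prof[1] * g0,
        profile.response_amp * prof[2] * g0,
        profile.response_amp * 0.8 * (0.15 + 0.85 * w1),
    ]
    kappas = [
        profile.plv_gain_f0[cond],
        profile.plv_gain_f0[cond] * 0.8,
        profile.plv_gain_f0[cond] * 0.6,
        profile.plv_gain_f1[(cond, v.label)],
    ]

    n_trials = 2 * n_per_polarity
    isi = rng.uniform(isi_s[0], isi_s[1], n_trials)
    min_gap = _EPOCH_PRE_S + _EPOCH_POST_S
    if np.any(isi < min_gap):
        raise ValueError("inter-stimulus interval shorter than the epoch window")
    onsets_s = 1.0 + np.concatenate([[0.0], np.cumsum(isi[:-1])])
    onsets = np.round(onsets_s * rate).astype(int)
    total = int(onsets[-1] + (min_gap + 0.2) * rate)

    x = _pink_noise(total, rate, profile.noise_level, rng, noise_exponent)

    # response template support: stimulus duration, 5 ms ramps, latency shift
    lat = int(round(profile.latency_ms * 1e-3 * rate))
    n_resp = int(round(v.duration * rate))
    t = np.arange(n_resp) / rate
    nr = int(round(0.005 * rate))
    ramp = np.ones(n_resp)
    ramp[:nr] = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    ramp[-nr:] = ramp[:nr][::-1]

    polarity = np.array(["A", "B"] * n_per_polarity)
    # Component mean phases share one subject-level reference phase plus a
    # fixed internal delay, so components that coincide in frequency (e.g.
    # the F1 TFS of /i/ at 260 Hz and the 2·f0 envelope harmonic) superpose
    # coherently instead of cancelling at random.
    global_phase = rng.uniform(0, 2 * np.pi)
    base_phase = global_phase - 2 * np.pi * np.asarray(freqs) * 0.003
    resp = np.zeros((n_trials, n_resp))
    for ci, (f, a, k, flip) in enumerate(zip(freqs, amps, kappas, flips)):
        mu = np.where(polarity == "B", base_phase[ci] + np.pi * flip, base_phase[ci])
        if np.isinf(k):
            ph = mu
        elif k == 0:
            ph = rng.uniform(0, 2 * np.pi, n_trials)
        else:
            ph = mu + rng.vonmises(0.0, k, n_trials)
        resp += a * np.sin(2 * np.pi * f * t[None, :] + ph[:, None])
    resp *= ramp[None, :]

    # artifacts: large slow transients somewhere inside the epoch window
    is_artifact = rng.random(n_trials) < profile.artifact_rate
    events = []
    for i, s in enumerate(onsets):
        x[s + lat : s + lat + n_resp] += resp[i]
        if is_artifact[i]:
            # burst with in-band oscillatory content so it survives the
            # 70-1000 Hz analysis bandpass and trips the ±70 μV rejection
            amp = rng.uniform(1.3, 2.2) * artifact_threshold * rng.choice([-1, 1])
            center = s + int(rng.uniform(0.0, 0.45) * rate)
            width = int(0.015 * rate)
            tt = np.arange(-3 * width, 3 * width)
            f_art = rng.uniform(90.0, 300.0)
            blob = amp * np.exp(-0.5 * (tt / width) ** 2) * np.cos(
                2 * np.pi * f_art * tt / rate
            )
            x[center - 3 * width : center + 3 * width] += blob
        events.append(Event(int(s), f"{v.label}|{cond}", polarity[i]))
    return ContinuousEEG(x, rate, events)


def simulate_behavior(
    profile: SubjectProfile,
    condition: str,
    words_per_step: int = 4,
    seed: int | None = None,
) -> BehavioralRun:
    """One BKB-SIN-style run: binomial key-word counts from a logistic
    psychometric function with midpoint at the subject's true SNR-50."""
    if condition not in profile.true_snr50:
        raise KeyError(f"no true threshold for condition {condition!r}")
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng([seed, CONDITIONS.index(condition), 29])
    mid = profile.true_snr50[condition]
    p = expit((SNR_STEPS - mid) / profile.psychometric_slope)
    correct = rng.binomial(words_per_step, p, size=(2, len(SNR_STEPS)))
    return BehavioralRun(condition, SNR_STEPS.copy(), correct, words_per_step)
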