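"""Vowel synthesis and bimodal (vocoder + lowpass) stimulus construction.

Builds the three steady-state vowels (/ε/, /i/, /ʊ/; shared f0 = 130 Hz,
F1 = 520/260/390 Hz) and transforms each into five bimodal listening
conditions: an eight-channel noise-vocoded signal for the "implanted"
(right) ear, optionally paired with a lowpass-filtered copy of the
original vowel for the "non-implanted" (left) ear at cutoffs of 125, 250,
500 or 750 Hz.  Channel edges for the vocoder follow the Greenwood
cochlear position-frequency map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "VowelSpec",
    "VocoderConfig",
    "BimodalStimulus",
    "DEFAULT_VOWELS",
    "CONDITIONS",
    "CONDITION_CUTOFFS",
    "REFERENCE_RMS",
    "synth_vowel",
    "greenwood_edges",
    "vocode",
    "lowpass_branch",
    "align_envelopes",
    "make_bimodal_set",
    "estimate_f0",
    "estimate_f1",
    "envelope_spectrum",
    "write_stimulus_wav",
    "read_wav",
]

#: Digital RMS standing in for the 80 dB SPL presentation level.  All level
#: rules are relative: the vocoded branch is normalized to this RMS and the
#: lowpass branch inherits the gain at which the *unfiltered* token sits at
#: this RMS (so narrow cutoffs are genuinely quieter).
REFERENCE_RMS = 0.05

# Greenwood human map constants: F(x) = A (10^(a x) - k), x in [0, 1].
_GREENWOOD_A = 165.4
_GREENWOOD_ALPHA = 2.1
_GREENWOOD_K = 0.88

CONDITIONS = ("Voc", "Voc+125", "Voc+250", "Voc+500", "Voc+750")
CONDITION_CUTOFFS = {
    "Voc": None,
    "Voc+125": 125.0,
    "Voc+250": 250.0,
    "Voc+500": 500.0,
    "Voc+750": 750.0,
}


@dataclass(frozen=True)
class AudioSignal:
    """A sampled mono waveform (dimensionless full-scale ±1.0)."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class VowelSpec:
    """Steady-state vowel description: label, pitch, first formant, length."""

    label: str
    f0: float = 130.0
    f1: float = 520.0
    duration: float = 0.39

    def __post_init__(self):
        if self.f1 <= self.f0:
            raise ValueError("F1 must exceed f0")
        if not (0.0 < self.duration <= 2.0):
            raise ValueError("implausible vowel duration")


#: The three vowel nuclei used throughout: F1 = 520, 260 and 390 Hz.
DEFAULT_VOWELS = (
    VowelSpec("ε", f0=130.0, f1=520.0),
    VowelSpec("i", f0=130.0, f1=260.0),
    VowelSpec("ʊ", f0=130.0, f1=390.0),
)


@dataclass(frozen=True)
class VocoderConfig:
    """Noise-vocoder parameters (defaults mimic an 8-channel CI simulation)."""

    n_channels: int = 8
    f_lo: float = 200.0
    f_hi: float = 7000.0
    env_cutoff: float = 400.0
    env_order: int = 4  # 4th order Butterworth -> 24 dB/octave
    analysis_order: int = 4
    envelope_mode: str = "halfwave"  # or "hilbert"
    refilter_carrier: bool = True


@dataclass(frozen=True)
class BimodalStimulus:
    """One vowel in one bimodal condition: vocoded right ear, lowpass left."""

    condition: str
    vowel: VowelSpec
    right: AudioSignal
    left: AudioSignal | None = None
    alignment_lag: int = 0

    def __post_init__(self):
        if self.condition not in CONDITION_CUTOFFS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.left is not None:
            if self.left.rate != self.right.rate:
                raise ValueError("left/right rate mismatch")
            if len(self.left.samples) != len(self.right.samples):
                raise ValueError("left/right length mismatch")

    @property
    def cutoff(self) -> float | None:
        return CONDITION_CUTOFFS[self.condition]


def _resonator_gain(f: np.ndarray, fc: float, bw: float) -> np.ndarray:
    """Magnitude of a unity-DC-gain second-order resonator at frequency f."""
    q = fc / bw
    num = fc**2
    den = np.sqrt((fc**2 - f**2) ** 2 + (fc * f / q) ** 2)
    return num / den


def synth_vowel(
    spec: VowelSpec,
    rate: float = 44100.0,
    *,
    max_harmonic_hz: float = 5000.0,
    f1_bandwidth: float = 60.0,
    f2: float = 1500.0,
    f2_bandwidth: float = 150.0,
    target_rms: float = REFERENCE_RMS,
) -> AudioSignal:
    """Source-filter synthesis of a steady vowel.

    A harmonic glottal-like source (amplitude 1/k per harmonic k, Schroeder
    phases) is shaped by a resonator at ``spec.f1`` plus a fixed higher
    resonator for naturalism, with 5 ms raised-cosine onset/offset ramps.
    The result measures f0 within 1 Hz (autocorrelation) and has its
    dominant sub-1 kHz spectral-envelope peak at F1.
    """
    if rate < 2.0 * max_harmonic_hz:
        raise ValueError(
            f"rate {rate} too low for harmonics up to {max_harmonic_hz} Hz"
        )
    n = int(round(spec.duration * rate))
    t = np.arange(n) / rate
    kmax = int(max_harmonic_hz // spec.f0)
    x = np.zeros(n)
    for k in range(1, kmax + 1):
        f = k * spec.f0
        amp = (1.0 / k) * _resonator_gain(np.array(f), spec.f1, f1_bandwidth) \
            * _resonator_gain(np.array(f), f2, f2_bandwidth)
        # phase-aligned harmonics: a glottal-pulse-like source whose temporal
        # envelope pulses at f0 (the periodicity the vocoder must transmit)
        x += float(amp) * np.cos(2 * np.pi * f * t)
    x *= _cos_ramp(n, rate, ramp_ms=5.0)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= target_rms / rms
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x /= peak
    return AudioSignal(x, rate)


def _cos_ramp(n: int, rate: float, ramp_ms: float = 5.0) -> np.ndarray:
    nr = min(int(round(ramp_ms * 1e-3 * rate)), n // 2)
    env = np.ones(n)
    if nr > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[-nr:] = r[::-1]
    return env


def _greenwood_x(f: np.ndarray) -> np.ndarray:
    """Inverse Greenwood map: cochlear position x in [0,1] for frequency f."""
    return np.log10(f / _GREENWOOD_A + _GREENWOOD_K) / _GREENWOOD_ALPHA


def greenwood_edges(n: int, f_lo: float, f_hi: float) -> np.ndarray:
    """n+1 channel edges equally spaced in Greenwood cochlear position.

    First edge is exactly ``f_lo`` and last exactly ``f_hi``.
    """
    if n < 1:
        raise ValueError("need at least one channel")
    if not (0 < f_lo < f_hi):
        raise ValueError("require 0 < f_lo < f_hi")
    x = np.linspace(_greenwood_x(np.array(f_lo)), _greenwood_x(np.array(f_hi)), n + 1)
    edges = _GREENWOOD_A * (10 ** (_GREENWOOD_ALPHA * x) - _GREENWOOD_K)
    edges[0], edges[-1] = f_lo, f_hi  # kill roundoff at the endpoints
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges not strictly increasing")
    return edges


def _bandpass_sos(lo: float, hi: float, rate: float, order: int):
    nyq = rate / 2.0
    if hi >= nyq:
        hi = 0.999 * nyq
    if hi / lo < 1.01:
        raise ValueError(f"channel ({lo:.1f}-{hi:.1f} Hz) too narrow to design")
    return sps.butter(order, [lo, hi], btype="band", fs=rate, output="sos")


def vocode(sig: AudioSignal, cfg: VocoderConfig = VocoderConfig(), seed: int = 0) -> AudioSignal:
    """Eight-channel (by default) white-noise vocoder.

    Per channel: bandpass analysis between Greenwood edges; envelope by
    half-wave rectification + 4th-order Butterworth lowpass at 400 Hz
    (24 dB/octave); envelope imposed on same-band-filtered white noise;
    channels summed and the sum RMS-matched to the input.  Deterministic
    under ``seed``.
    """
    if sig.rate < 2.0 * cfg.f_hi:
        raise ValueError("sampling rate below 2×f_hi")
    edges = greenwood_edges(cfg.n_channels, cfg.f_lo, cfg.f_hi)
    rng = np.random.default_rng(seed)
    x = sig.samples
    env_sos = sps.butter(cfg.env_order, cfg.env_cutoff, btype="low", fs=sig.rate, output="sos")
    out = np.zeros_like(x)
    for lo, hi in zip(edges[:-1], edges[1:]):
        band_sos = _bandpass_sos(lo, hi, sig.rate, cfg.analysis_order)
        band = sps.sosfilt(band_sos, x)
        if cfg.envelope_mode == "hilbert":
            env = np.abs(sps.hilbert(band))
            env = sps.sosfilt(env_sos, env)
        else:
            env = sps.sosfilt(env_sos, np.maximum(band, 0.0))
        env = np.maximum(env, 0.0)
        carrier = sps.sosfilt(band_sos, rng.standard_normal(len(x)))
        chan = env * carrier
        if cfg.refilter_carrier:
            chan = sps.sosfilt(band_sos, chan)
        out += chan
    in_rms = np.sqrt(np.mean(x**2))
    out_rms = np.sqrt(np.mean(out**2))
    if in_rms == 0 or out_rms == 0:
        return AudioSignal(np.zeros_like(x), sig.rate)
    out *= in_rms / out_rms
    return AudioSignal(out, sig.rate)


def lowpass_branch(sig: AudioSignal, cutoff: float, order: int = 8) -> AudioSignal:
    """Lowpass the original token (8th-order Butterworth, 48 dB/octave).

    No re-normalization: the branch keeps the gain at which the unfiltered
    token sits at reference level, so low cutoffs carry less energy.
    """
    if cutoff >= sig.rate / 2.0:
        raise ValueError("cutoff at or above Nyquist")
    if cutoff not in (125.0, 250.0, 500.0, 750.0):
        warnings.warn(f"non-standard lowpass cutoff {cutoff} Hz", stacklevel=2)
    sos = sps.butter(order, cutoff, btype="low", fs=sig.rate, output="sos")
    return AudioSignal(sps.sosfilt(sos, sig.samples), sig.rate)


def _smooth_envelope(x: np.ndarray, rate: float, cutoff: float = 50.0) -> np.ndarray:
    sos = sps.butter(2, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.abs(x))


def align_envelopes(
    vocoded: AudioSignal, lowpassed: AudioSignal, max_lag_ms: float = 20.0
) -> tuple[int, AudioSignal]:
    """Temporal-envelope alignment of the two ears by cross-correlation.

    Returns ``(lag, shifted)`` where ``shifted`` is ``lowpassed`` delayed by
    ``lag`` samples (negative lag advances it) and zero-padded back to the
    original length.  The lag maximizes the cross-correlation of the two
    smoothed rectified envelopes within ±``max_lag_ms``.
    """
    if vocoded.rate != lowpassed.rate:
        raise ValueError("rate mismatch")
    ev = _smooth_envelope(vocoded.samples, vocoded.rate)
    el = _smooth_envelope(lowpassed.samples, lowpassed.rate)
    if not np.any(ev) or not np.any(el):
        raise ValueError("all-zero envelope; cannot align")
    w = int(round(max_lag_ms * 1e-3 * vocoded.rate))
    n = min(len(ev), len(el))
    ev, el = ev[:n], el[:n]
    best_d, best_score = 0, -np.inf
    for d in range(-w, w + 1):
        # normalized correlation of ev[t] with el[t + d] over the overlap
        if d >= 0:
            a, b = ev[: n - d], el[d:]
        else:
            a, b = ev[-d:], el[: n + d]
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        score = float(np.dot(a, b) / denom) if denom > 0 else -np.inf
        if score > best_score:
            best_score, best_d = score, d
    lag = -best_d
    shifted = np.zeros_like(lowpassed.samples)
    m = len(shifted)
    if lag >= 0:
        shifted[lag:] = lowpassed.samples[: m - lag]
    else:
        shifted[: m + lag] = lowpassed.samples[-lag:]
    return lag, AudioSignal(shifted, lowpassed.rate)


def make_bimodal_set(
    vowels: tuple[VowelSpec, ...] = DEFAULT_VOWELS,
    cutoffs: tuple[float | None, ...] = (None, 125.0, 250.0, 500.0, 750.0),
    cfg: VocoderConfig = VocoderConfig(),
    seed: int = 0,
    rate: float = 44100.0,
) -> list[BimodalStimulus]:
    """All vowel × condition stimuli (3 × 5 = 15 at defaults).

    The vocoded right-ear branch of a given vowel is bit-identical across
    its five conditions (same carrier-noise seed).
    """
    out = []
    for vi, spec in enumerate(vowels):
        token = synth_vowel(spec, rate)
        voc = vocode(token, cfg, seed=seed * 1000 + vi)
        for cut in cutoffs:
            if cut is None:
                out.append(BimodalStimulus("Voc", spec, right=voc))
            else:
                lp = lowpass_branch(token, cut)
                lag, shifted = align_envelopes(voc, lp)
                cond = f"Voc+{int(cut)}"
                out.append(
                    BimodalStimulus(cond, spec, right=voc, left=shifted, alignment_lag=lag)
                )
    return out


# ---------------------------------------------------------------------------
# Measurement helpers (stimulus verification)

def estimate_f0(
    sig: AudioSignal, fmin: float = 80.0, fmax: float = 300.0,
    window: tuple[float, float] | None = None,
) -> float:
    """Pitch by autocorrelation peak with parabolic interpolation (Hz)."""
    x = sig.samples
    if window is not None:
        i0, i1 = (int(round(w * sig.rate)) for w in window)
        x = x[i0:i1]
    x = x - np.mean(x)
    ac = sps.correlate(x, x, mode="full")[len(x) - 1 :]
    lo = int(sig.rate / fmax)
    hi = int(sig.rate / fmin)
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    # parabolic refinement around the peak
    if 0 < k < len(ac) - 1:
        y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return float(sig.rate / (k + delta))


def estimate_f1(
    sig: AudioSignal, fmax: float = 1000.0, smooth_hz: float = 40.0
) -> float:
    """Dominant sub-1 kHz peak of the smoothed amplitude-spectrum envelope (Hz)."""
    x = sig.samples * np.hanning(len(sig.samples))
    nfft = int(2 ** np.ceil(np.log2(len(x) * 4)))
    spec = np.abs(np.fft.rfft(x, nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / sig.rate)
    df = freqs[1] - freqs[0]
    # Gaussian smoothing of the magnitude spectrum
    half = int(3 * smooth_hz / df)
    g = np.exp(-0.5 * (np.arange(-half, half + 1) * df / smooth_hz) ** 2)
    g /= g.sum()
    env = np.convolve(spec, g, mode="same")
    band = freqs < fmax
    k = int(np.argmax(env[band]))
    if 0 < k < band.sum() - 1:
        y0, y1, y2 = env[k - 1], env[k], env[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return float((k + delta) * df)


def envelope_spectrum(
    sig: AudioSignal, window: tuple[float, float] = (0.05, 0.35)
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude spectrum of the steady-state Hilbert temporal envelope.

    Used to verify that vocoded stimuli carry f0 periodicity in their
    envelope.  Returns (frequencies, magnitudes), DC removed.
    """
    i0, i1 = (int(round(w * sig.rate)) for w in window)
    x = sig.samples[i0:i1]
    env = np.abs(sps.hilbert(x))
    env = env - env.mean()
    freqs = np.fft.rfftfreq(len(env), 1.0 / sig.rate)
    return freqs, np.abs(np.fft.rfft(env))


# ---------------------------------------------------------------------------
# WAV I/O (float32; stereo convention: left = lowpass, right = vocoded)

def write_stimulus_wav(path, stim: BimodalStimulus) -> None:
    right = stim.right.samples
    left = stim.left.samples if stim.left is not None else np.zeros_like(right)
    data = np.stack([left, right], axis=1).astype(np.float32)
    wavfile.write(path, int(stim.right.rate), data)


def read_wav(path) -> AudioSignal | tuple[AudioSignal, AudioSignal]:
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        return AudioSignal(data, rate)
    return AudioSignal(data[:, 0], rate), AudioSignal(data[:, 1], rate)
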