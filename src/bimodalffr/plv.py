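"""Phase-locking value (PLV) spectrograms and spectra.

The PLV at a time-frequency point is the magnitude of the mean unit phase
vector across trials: each cleaned single-trial epoch is short-time
Fourier transformed with 60 ms sliding windows hopped every 1 ms and
zero-padded to 1 Hz (interpolated) frequency resolution; per-trial
magnitudes are normalized to 1 and the N unit vectors are averaged.
A PLV of 0 means no phase coherence across trials, 1 means perfect
coherence.  The measure is invariant to per-trial amplitude scaling.

Time-averaging over the 150-250 ms steady state and averaging the two
polarity spectra yields the PLV spectrum; the same computation on the
prestimulus (-50-0 ms) interval yields the empirical noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet, EPOCH_PRE_MS
from .stimuli import DEFAULT_VOWELS, VowelSpec

__all__ = [
    "PLVSpectrogram",
    "PLVSpectrum",
    "BenefitRecord",
    "trial_spectrogram",
    "plv",
    "plv_spectrum",
    "noise_floor",
    "neural_benefit",
    "WINDOW_MS",
    "HOP_MS",
    "F_MAX",
]

WINDOW_MS = 60.0
HOP_MS = 1.0
F_MAX = 1000.0
F0_HZ = 130.0


@dataclass(frozen=True)
class PLVSpectrogram:
    """PLV on a (window-center time) × (1 Hz frequency) lattice, values in [0,1]."""

    values: np.ndarray  # (n_times, n_freqs)
    times_ms: np.ndarray  # window centers, relative to stimulus onset
    freqs: np.ndarray
    n_trials: int
    polarity: str

    def __post_init__(self):
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-9):
            raise ValueError("PLV values must lie in [0, 1]")


@dataclass(frozen=True)
class PLVSpectrum:
    """Time-averaged, polarity-averaged PLV per 1 Hz bin, with noise floor."""

    values: np.ndarray
    freqs: np.ndarray
    n_trials: int
    noise_floor: np.ndarray | None = None

    def at(self, freq_hz: float) -> float:
        k = int(np.argmin(np.abs(self.freqs - freq_hz)))
        return float(self.values[k])

    def floor_at(self, freq_hz: float) -> float:
        if self.noise_floor is None:
            raise ValueError("no noise floor attached")
        k = int(np.argmin(np.abs(self.freqs - freq_hz)))
        return float(self.noise_floor[k])


@dataclass(frozen=True)
class BenefitRecord:
    """Per-subject bimodal-benefit values feeding the regression."""

    subject: int
    f0_benefit: float  # ΔPLV at 130 Hz, Voc+750 − Voc, vowel-averaged
    f1_benefit: float  # ΔPLV at each vowel's F1, vowel-averaged
    behavioral_benefit: float  # dB SNR, Voc − Voc+750

    def __post_init__(self):
        if not (-1.0 <= self.f0_benefit <= 1.0 and -1.0 <= self.f1_benefit <= 1.0):
            raise ValueError("ΔPLV outside [-1, 1]")


def _window_grid(n_samples: int, rate: float, hop_ms: float = HOP_MS):
    win = int(round(WINDOW_MS * 1e-3 * rate))
    hop = max(int(round(hop_ms * 1e-3 * rate)), 1)
    if n_samples < win:
        raise ValueError("epoch shorter than one analysis window")
    starts = np.arange(0, n_samples - win + 1, hop)
    centers_ms = (starts + win / 2.0) / rate * 1e3 - EPOCH_PRE_MS
    return win, starts, centers_ms


def trial_spectrogram(
    epoch_uv: np.ndarray,
    rate: float = 10_000.0,
    hop_ms: float = HOP_MS,
    f_max: float = F_MAX,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex STFT of one epoch: 60 ms windows, ``hop_ms`` hop, zero-padded
    to 1 Hz bins.  Returns (complex array (n_windows, n_freqs), window-center
    times in ms relative to onset, frequency axis in Hz).  Only full windows
    are used.  Magnitude normalization is deferred to :func:`plv`.
    """
    x = np.asarray(epoch_uv, dtype=float)
    win, starts, centers = _window_grid(len(x), rate, hop_ms)
    nfft = int(round(rate))  # zero-pad to 1 Hz resolution
    segs = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    spec = np.fft.rfft(segs, nfft, axis=-1)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    keep = freqs <= f_max
    return spec[:, keep], centers, freqs[keep]


def plv(
    epochs: EpochSet,
    polarity: str,
    hop_ms: float = HOP_MS,
    f_max: float = F_MAX,
    t_range_ms: tuple[float, float] | None = None,
    chunk: int = 16,
) -> PLVSpectrogram:
    """PLV(t, f) = |(1/N) Σ_n exp(i φ_n(t, f))| over the N retained trials.

    Zero-magnitude bins contribute a zero vector without reducing N (a
    conservative choice).  ``t_range_ms`` restricts computation to windows
    whose centers fall in the given interval.
    """
    trials = epochs.retained(polarity)
    if len(trials) < 2:
        raise ValueError("need at least two retained trials")
    rate = epochs.rate
    win, starts, centers = _window_grid(trials.shape[1], rate, hop_ms)
    if t_range_ms is not None:
        sel = (centers >= t_range_ms[0]) & (centers <= t_range_ms[1])
        starts, centers = starts[sel], centers[sel]
        if len(starts) == 0:
            raise ValueError("no analysis windows inside t_range_ms")
    nfft = int(round(rate))
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    keep = freqs <= f_max
    freqs = freqs[keep]
    acc = np.zeros((len(starts), keep.sum()), dtype=complex)
    n = len(trials)
    for i0 in range(0, n, chunk):
        block = trials[i0 : i0 + chunk]
        segs = np.lib.stride_tricks.sliding_window_view(block, win, axis=1)[:, starts]
        spec = np.fft.rfft(segs, nfft, axis=-1)[..., keep]
        mag = np.abs(spec)
        phasors = np.divide(spec, mag, out=np.zeros_like(spec), where=mag > 0)
        acc += phasors.sum(axis=0)
    values = np.abs(acc) / n
    return PLVSpectrogram(np.clip(values, 0.0, 1.0), centers, freqs, n, polarity)


def plv_spectrum(
    spg_a: PLVSpectrogram,
    spg_b: PLVSpectrogram | None = None,
    window_ms: tuple[float, float] = (150.0, 250.0),
    floor: np.ndarray | None = None,
) -> PLVSpectrum:
    """Time-mean over windows centered in ``window_ms``, then mean of the
    two polarity spectra (PLVs, not complex vectors, are averaged)."""
    spgs = [spg_a] if spg_b is None else [spg_a, spg_b]
    if spg_b is not None and (
        len(spg_a.freqs) != len(spg_b.freqs)
        or not np.allclose(spg_a.freqs, spg_b.freqs)
    ):
        raise ValueError("polarity spectrogram grids do not match")
    means = []
    for s in spgs:
        sel = (s.times_ms >= window_ms[0]) & (s.times_ms <= window_ms[1])
        if not np.any(sel):
            raise ValueError("no windows centered inside the analysis range")
        means.append(s.values[sel].mean(axis=0))
    values = np.mean(means, axis=0)
    n = int(np.mean([s.n_trials for s in spgs]))
    return PLVSpectrum(values, spg_a.freqs.copy(), n, floor)


def noise_floor(
    epochs: EpochSet,
    f_max: float = F_MAX,
) -> np.ndarray:
    """Per-bin PLV floor from the prestimulus (-50-0 ms) interval.

    The 60 ms analysis window does not fit in 50 ms of prestimulus data,
    so a single window anchored at 0 ms is used with the missing 10 ms
    zero-padded.  (For PLV this is numerically identical to analyzing the
    native 50 ms window: zero-padding only multiplies each trial's spectrum
    by the same linear phase factor, which cancels in the resultant.)
    Polarity floors are averaged.  A response bin counts as a true response
    only when its PLV exceeds this floor.
    """
    rate = epochs.rate
    pre = int(round(EPOCH_PRE_MS * 1e-3 * rate))
    nfft = int(round(rate))
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    keep = freqs <= f_max
    floors = []
    for pol in ("A", "B"):
        trials = epochs.retained(pol)
        if len(trials) == 0:
            continue
        seg = trials[:, :pre]
        spec = np.fft.rfft(seg, nfft, axis=-1)[:, keep]
        mag = np.abs(spec)
        phasors = np.divide(spec, mag, out=np.zeros_like(spec), where=mag > 0)
        floors.append(np.abs(phasors.mean(axis=0)))
    if not floors:
        raise ValueError("no retained trials")
    return np.mean(floors, axis=0)


def neural_benefit(
    plv_by_condition: dict[str, dict[str, PLVSpectrum]],
    vowels: tuple[VowelSpec, ...] = DEFAULT_VOWELS,
    rich: str = "Voc+750",
    sparse: str = "Voc",
    fisher_first: bool = False,
) -> tuple[float, float]:
    """Across-vowel averaged ΔPLV (rich − sparse) at f0 and at each vowel's F1.

    With ``fisher_first`` the raw PLVs are Fisher-z transformed *before*
    differencing (the default differences raw PLVs; the downstream
    regression applies Fisher z to the differences).
    """
    for cond in (rich, sparse):
        if cond not in plv_by_condition:
            raise KeyError(f"missing PLV spectra for condition {cond!r}")
    tr = (lambda x: float(np.arctanh(min(x, 0.999999)))) if fisher_first else float
    f0_deltas, f1_deltas = [], []
    for v in vowels:
        hi = plv_by_condition[rich][v.label]
        lo = plv_by_condition[sparse][v.label]
        f0_deltas.append(tr(hi.at(F0_HZ)) - tr(lo.at(F0_HZ)))
        f1_deltas.append(tr(hi.at(v.f1)) - tr(lo.at(v.f1)))
    return float(np.mean(f0_deltas)), float(np.mean(f1_deltas))
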