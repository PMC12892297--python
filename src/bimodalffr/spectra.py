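"""FFR amplitude spectra from the steady-state window of averaged waveforms.

The 100 ms steady-state segment (150-250 ms) of a polarity-A grand average
is zero-padded to 2500 samples at 10 kHz, giving a 4 Hz bin width; the
single-sided amplitude spectrum is truncated to 250 points covering
0-996 Hz.  Scaling is calibrated so a pure sinusoid of amplitude a μV
fully inside the window reports ≈ a μV at its bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AverageWaveform, EPOCH_PRE_MS

__all__ = [
    "FFRSpectrum",
    "ComponentAmplitude",
    "ffr_spectrum",
    "component_amplitude",
    "N_BINS",
    "BIN_HZ",
    "STEADY_STATE_MS",
]

N_BINS = 250
BIN_HZ = 4.0
STEADY_STATE_MS = (150.0, 250.0)


@dataclass(frozen=True)
class FFRSpectrum:
    """250-point single-sided amplitude spectrum, 0-996 Hz at 4 Hz spacing."""

    amplitudes: np.ndarray
    source: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if self.amplitudes.shape != (N_BINS,):
            raise ValueError(f"spectrum must have exactly {N_BINS} points")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(N_BINS) * BIN_HZ


@dataclass(frozen=True)
class ComponentAmplitude:
    requested_hz: float
    bin_hz: float
    amplitude: float


def ffr_spectrum(
    avg: AverageWaveform,
    window_ms: tuple[float, float] = STEADY_STATE_MS,
    source: tuple = (),
    taper: str | None = None,
) -> FFRSpectrum:
    """FFT amplitude spectrum of the ``window_ms`` segment of an average.

    The segment is zero-padded to ``rate / BIN_HZ`` samples (2500 at
    10 kHz).  ``taper`` may be "hann"; default is rectangular, appropriate
    for a steady-state segment.
    """
    rate = avg.rate
    i0 = int(round((window_ms[0] + EPOCH_PRE_MS) * 1e-3 * rate))
    i1 = int(round((window_ms[1] + EPOCH_PRE_MS) * 1e-3 * rate))
    if i0 < 0 or i1 > len(avg.samples) or i1 <= i0:
        raise ValueError("analysis window outside the averaged epoch")
    seg = avg.samples[i0:i1]
    n = len(seg)
    if taper == "hann":
        w = np.hanning(n)
        seg = seg * w
        scale = 2.0 / w.sum()
    elif taper is None:
        scale = 2.0 / n
    else:
        raise ValueError(f"unknown taper {taper!r}")
    nfft = int(round(rate / BIN_HZ))
    amps = scale * np.abs(np.fft.rfft(seg, nfft))
    return FFRSpectrum(amps[:N_BINS], source)


def component_amplitude(spec: FFRSpectrum, target_hz: float, local_max: bool = False) -> ComponentAmplitude:
    """Amplitude at the bin nearest ``target_hz`` (ties break to the lower bin).

    With ``local_max`` the largest of the nearest bin and its two
    neighbours is reported instead.
    """
    if not (0 <= target_hz < N_BINS * BIN_HZ):
        raise ValueError("target outside the 0-1000 Hz spectrum")
    lower = int(target_hz // BIN_HZ)
    # nearest bin; exact midpoints resolve toward the lower bin
    if lower + 1 < N_BINS and (target_hz - lower * BIN_HZ) > BIN_HZ / 2.0:
        k = lower + 1
    else:
        k = lower
    if local_max:
        cands = [j for j in (k - 1, k, k + 1) if 0 <= j < N_BINS]
        k = max(cands, key=lambda j: spec.amplitudes[j])
    return ComponentAmplitude(target_hz, k * BIN_HZ, float(spec.amplitudes[k]))
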