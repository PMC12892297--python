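"""Continuous EEG -> cleaned, polarity-labeled epochs and averages.

Reduction chain: zero-phase 70-1000 Hz bandpass, epoching from -50 to
+500 ms around stimulus onset, per-epoch linear detrend, ±70 μV artifact
rejection, baseline correction on the prestimulus interval, and
polarity-resolved averaging (A, B, (A+B)/2, (A-B)/2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .cohort import ContinuousEEG, Event

__all__ = [
    "EpochSet",
    "AverageWaveform",
    "bandpass",
    "epoch",
    "clean",
    "average",
    "EPOCH_PRE_MS",
    "EPOCH_POST_MS",
    "REJECT_UV",
]

EPOCH_PRE_MS = 50.0
EPOCH_POST_MS = 500.0
REJECT_UV = 70.0


@dataclass
class EpochSet:
    """Trial × time matrix (μV) with polarity labels and a rejection mask.

    The time axis is the half-open window [-50, 500) ms relative to
    stimulus onset: exactly 5500 samples at 10 kHz.
    """

    trials: np.ndarray  # (n_trials, n_samples)
    polarity: np.ndarray  # (n_trials,) of "A"/"B"
    rejected: np.ndarray  # (n_trials,) bool
    rate: float

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        self.polarity = np.asarray(self.polarity)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        n = self.trials.shape[0]
        if len(self.polarity) != n or len(self.rejected) != n:
            raise ValueError("label/mask length mismatch")

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(self.n_samples) / self.rate) * 1e3 - EPOCH_PRE_MS

    def retained(self, polarity: str | None = None) -> np.ndarray:
        keep = ~self.rejected
        if polarity is not None:
            keep &= self.polarity == polarity
        return self.trials[keep]


@dataclass(frozen=True)
class AverageWaveform:
    polarity: str  # "A", "B", "A+B", "A-B"
    samples: np.ndarray
    n_trials: int
    rate: float

    @property
    def times_ms(self) -> np.ndarray:
        return (np.arange(len(self.samples)) / self.rate) * 1e3 - EPOCH_PRE_MS


def bandpass(
    continuous: ContinuousEEG, lo: float = 70.0, hi: float = 1000.0, order: int = 4
) -> ContinuousEEG:
    """Zero-phase Butterworth bandpass (order ``order`` per edge)."""
    nyq = continuous.rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError("invalid band edges")
    sos = sps.butter(order, [lo, hi], btype="band", fs=continuous.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, continuous.samples)
    return ContinuousEEG(filtered, continuous.rate, list(continuous.events))


def epoch(continuous: ContinuousEEG, events: list[Event] | None = None) -> EpochSet:
    """One epoch per event over the half-open [-50, 500) ms window."""
    if events is None:
        events = continuous.events
    rate = continuous.rate
    pre = int(round(EPOCH_PRE_MS * 1e-3 * rate))
    post = int(round(EPOCH_POST_MS * 1e-3 * rate))
    n = pre + post
    trials, pols = [], []
    for ev in events:
        start = ev.sample - pre
        stop = ev.sample + post
        if start < 0 or stop > len(continuous.samples):
            raise ValueError(
                f"event at sample {ev.sample} ({ev.stimulus}, {ev.polarity}) "
                "lacks a full epoch window"
            )
        trials.append(continuous.samples[start:stop])
        pols.append(ev.polarity)
    trials = np.asarray(trials)
    assert trials.shape[1] == n
    return EpochSet(trials, np.asarray(pols), np.zeros(len(events), bool), rate)


def clean(
    epochs: EpochSet, reject_uv: float = REJECT_UV
) -> EpochSet:
    """Detrend -> reject at ±``reject_uv`` -> baseline-correct, in that order.

    Detrending removes a per-epoch least-squares line; rejection flags any
    epoch whose detrended amplitude exceeds the threshold anywhere; baseline
    correction subtracts the mean of the prestimulus (-50-0 ms) segment
    from the retained epochs.  Idempotent.
    """
    x = sps.detrend(epochs.trials, axis=1, type="linear")
    rejected = np.max(np.abs(x), axis=1) > reject_uv
    if np.all(rejected):
        raise ValueError("all trials rejected at ±%g μV" % reject_uv)
    pre = int(round(EPOCH_PRE_MS * 1e-3 * epochs.rate))
    baseline = x[:, :pre].mean(axis=1, keepdims=True)
    x = x - baseline
    return EpochSet(x, epochs.polarity.copy(), rejected, epochs.rate)


def average(epochs: EpochSet, mode: str = "A") -> AverageWaveform:
    """Mean over retained trials.

    Modes: "A", "B" (single polarity), "sum" ((A+B)/2, envelope-emphasizing)
    and "difference" ((A-B)/2, TFS-emphasizing).
    """
    if mode in ("A", "B"):
        kept = epochs.retained(mode)
        if len(kept) == 0:
            raise ValueError(f"no retained trials of polarity {mode}")
        return AverageWaveform(mode, kept.mean(axis=0), len(kept), epochs.rate)
    if mode in ("sum", "difference"):
        a = epochs.retained("A")
        b = epochs.retained("B")
        if len(a) == 0 or len(b) == 0:
            raise ValueError("need retained trials of both polarities")
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        samples = (ma + mb) / 2.0 if mode == "sum" else (ma - mb) / 2.0
        label = "A+B" if mode == "sum" else "A-B"
        return AverageWaveform(label, samples, len(a) + len(b), epochs.rate)
    raise ValueError(f"unknown averaging mode {mode!r}")
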