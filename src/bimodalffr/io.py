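"""On-disk containers for continuous recordings and epoch sets.

A recording is stored as three files sharing a prefix: ``<p>.samples.npy``
(float32 μV), ``<p>.events.tsv`` (sample index, stimulus id, polarity) and
``<p>.meta.json`` (rate, counts).  Epoch sets use ``<p>.trials.npy`` plus a
TSV of per-trial polarity/rejection flags and the same JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ContinuousEEG, Event
from .preprocess import EpochSet

__all__ = [
    "save_continuous",
    "load_continuous",
    "save_epochs",
    "load_epochs",
]


def save_continuous(prefix, eeg: ContinuousEEG) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(f"{prefix}.samples.npy", eeg.samples.astype(np.float32))
    pd.DataFrame(
        [(e.sample, e.stimulus, e.polarity) for e in eeg.events],
        columns=["sample", "stimulus", "polarity"],
    ).to_csv(f"{prefix}.events.tsv", sep="\t", index=False)
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(
            {"rate_hz": eeg.rate, "n_samples": len(eeg.samples),
             "n_events": len(eeg.events), "units": "uV"},
            fh,
        )


def load_continuous(prefix) -> ContinuousEEG:
    prefix = Path(prefix)
    samples = np.load(f"{prefix}.samples.npy").astype(float)
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    ev = pd.read_csv(f"{prefix}.events.tsv", sep="\t")
    events = [
        Event(int(r.sample), str(r.stimulus), str(r.polarity))
        for r in ev.itertuples()
    ]
    return ContinuousEEG(samples, float(meta["rate_hz"]), events)


def save_epochs(prefix, epochs: EpochSet) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(f"{prefix}.trials.npy", epochs.trials.astype(np.float32))
    pd.DataFrame(
        {"polarity": epochs.polarity, "rejected": epochs.rejected}
    ).to_csv(f"{prefix}.labels.tsv", sep="\t", index=False)
    with open(f"{prefix}.meta.json", "w") as fh:
        json.dump(
            {"rate_hz": epochs.rate, "n_trials": len(epochs.polarity),
             "n_samples": epochs.n_samples, "units": "uV"},
            fh,
        )


def load_epochs(prefix) -> EpochSet:
    prefix = Path(prefix)
    trials = np.load(f"{prefix}.trials.npy").astype(float)
    labels = pd.read_csv(f"{prefix}.labels.tsv", sep="\t")
    with open(f"{prefix}.meta.json") as fh:
        meta = json.load(fh)
    return EpochSet(
        trials,
        labels.polarity.to_numpy(),
        labels.rejected.to_numpy(bool),
        float(meta["rate_hz"]),
    )
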