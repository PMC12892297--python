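#!/usr/bin/env python
"""Simulate one synthetic subject end to end and inspect the measurements.

Generates continuous EEG for one subject listening to /i/ in the
vocoder-only and widest-bandwidth conditions (200 trials per polarity),
preprocesses it (70-1000 Hz bandpass, epoching, ±70 μV rejection), and
prints the FFR component amplitudes and PLVs against the prestimulus
noise floor.  Finding: adding the 750 Hz acoustic ear raises the F1
(260 Hz) amplitude and PLV well above the vocoder-only values, while the
noise floor stays near the 1/√N resultant scale.
"""

from pathlib import Path

import pandas as pd

from bimodalffr import cohort as co
from bimodalffr import pipeline as pipe
from bimodalffr import stimuli as st

OUT = Path("results/example_subject")
OUT.mkdir(parents=True, exist_ok=True)

profile = co.make_cohort(6, seed=1)[0]
stimuli = [s for s in st.make_bimodal_set(seed=1) if s.vowel.label == "i"]

amp_rows, plv_rows, _, _ = pipe.subject_tables(
    profile, stimuli, ("Voc", "Voc+750"), ("Voc", "Voc+750"), 200
)
amps = pd.DataFrame(amp_rows)
plvs = pd.DataFrame(plv_rows)
amps.to_csv(OUT / "component_amplitudes.csv", index=False)
plvs.to_csv(OUT / "plv_components.csv", index=False)

print("FFR component amplitudes (μV), subject 0, vowel /i/:")
print(amps.pivot_table(index="condition", columns="component", values="amplitude_uv").round(4))
print("\nPLV at f0/F1 vs prestimulus floor:")
print(
    plvs.pivot_table(
        index="condition", columns="component", values=["plv", "noise_floor"]
    ).round(3)
)
print(f"\ntables written to {OUT}/")
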