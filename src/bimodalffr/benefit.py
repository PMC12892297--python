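"""Behavioral scoring and the neural -> perceptual benefit regression.

SNR-50 thresholds are estimated from key-words-correct counts with the
Spearman-Kärber formula; perceptual bimodal benefit is the threshold
difference between the vocoder-only and widest-bandwidth conditions.
Perceptual benefit is regressed on Fisher-z-transformed neural (ΔPLV)
benefit at f0 and F1 by ordinary least squares, with variance inflation
factors as the collinearity diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .cohort import BehavioralRun, SNR_STEPS
from .plv import BenefitRecord

__all__ = [
    "SNRThreshold",
    "RegressionResult",
    "snr50",
    "perceptual_benefit",
    "fisher_z",
    "vif",
    "regress_benefit",
]


@dataclass(frozen=True)
class SNRThreshold:
    condition: str
    list_pair_snr50: tuple[float, float]
    threshold: float  # mean of the two list pairs, dB


@dataclass(frozen=True)
class RegressionResult:
    params: pd.Series
    r2: float
    r2_adj: float
    f_stat: float
    f_pvalue: float
    df: tuple[int, int]
    t_pvalues: pd.Series
    vif: pd.Series | None

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("R² outside [0, 1]")


def snr50(run: BehavioralRun, words_per_step: int | None = None) -> SNRThreshold:
    """Spearman-Kärber SNR-50 per list pair, averaged.

    SNR-50 = top SNR + step/2 − step × (total correct / words per step),
    for the +21 → 0 dB ladder in 3 dB steps.  All words correct gives
    −1.5 dB; none correct gives +22.5 dB.
    """
    if words_per_step is None:
        words_per_step = run.words_per_step
    snrs = np.asarray(run.snr_db, dtype=float)
    if len(snrs) != len(SNR_STEPS) or not np.allclose(np.diff(snrs), -3.0):
        raise ValueError("expected 8 SNR steps from +21 to 0 dB in -3 dB steps")
    step = 3.0
    top = snrs[0]
    pair_thresholds = tuple(
        float(top + step / 2.0 - step * counts.sum() / words_per_step)
        for counts in run.correct
    )
    return SNRThreshold(run.condition, pair_thresholds, float(np.mean(pair_thresholds)))


def perceptual_benefit(
    thresholds: dict[str, SNRThreshold], rich: str = "Voc+750", sparse: str = "Voc"
) -> float:
    """Benefit in dB = threshold(vocoder-only) − threshold(widest bandwidth);
    positive values mean the acoustic ear improved speech-in-noise."""
    for cond in (sparse, rich):
        if cond not in thresholds:
            raise KeyError(f"missing scored condition {cond!r}")
    return float(thresholds[sparse].threshold - thresholds[rich].threshold)


def fisher_z(x: float) -> float:
    """Fisher z transform, atanh(x); defined on (−1, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= 1.0):
        raise ValueError("Fisher z requires |x| < 1")
    out = np.arctanh(x)
    return float(out) if out.ndim == 0 else out


def vif(predictors: np.ndarray, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per predictor: VIF_j = 1/(1 − R²_j) from
    regressing predictor j on the others (with intercept)."""
    x = np.asarray(predictors, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need at least two predictors")
    if x.shape[0] <= x.shape[1] + 1:
        raise ValueError("too few observations for VIF")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) <= x.shape[1]:
        raise ValueError("perfectly collinear predictors (infinite VIF)")
    xc = sm.add_constant(x)
    vals = [variance_inflation_factor(xc, j + 1) for j in range(x.shape[1])]
    if names is None:
        names = [f"x{j}" for j in range(x.shape[1])]
    return pd.Series(vals, index=names, name="VIF")


def regress_benefit(
    records: list[BenefitRecord],
    predictors: tuple[str, ...] = ("f0", "F1"),
    fisher: bool = True,
) -> RegressionResult:
    """OLS of perceptual benefit on Fisher-z neural benefit at f0 and/or F1.

    Reports R², adjusted R², the overall F test, per-predictor t tests and
    (for the two-predictor model) VIFs.
    """
    if not set(predictors) <= {"f0", "F1"}:
        raise ValueError("predictors must be a subset of {'f0', 'F1'}")
    n = len(records)
    if n < len(predictors) + 2:
        raise ValueError("too few records for the requested model")
    cols = {}
    if "f0" in predictors:
        cols["f0"] = np.array([r.f0_benefit for r in records])
    if "F1" in predictors:
        cols["F1"] = np.array([r.f1_benefit for r in records])
    x = pd.DataFrame(cols)
    if fisher:
        x = x.apply(lambda col: np.arctanh(np.clip(col, -0.999999, 0.999999)))
    y = np.array([r.behavioral_benefit for r in records])
    xc = sm.add_constant(x)
    if np.linalg.matrix_rank(xc.to_numpy()) < xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, xc).fit()
    vifs = vif(x.to_numpy(), list(x.columns)) if x.shape[1] >= 2 else None
    return RegressionResult(
        params=fit.params,
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        t_pvalues=fit.pvalues.drop("const"),
        vif=vifs,
    )
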