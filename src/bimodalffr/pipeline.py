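"""End-to-end orchestration: stimuli -> synthetic cohort -> preprocessing ->
spectra & PLV -> classification -> benefit regression.

A declarative :class:`RunConfig` (loadable from YAML) drives
:func:`run_pipeline`, which executes the stages in dependency order,
writes tidy tables under the configured output root, and returns a
:class:`RunResult` carrying the in-memory objects plus a manifest of
everything written.  All randomness derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benefit as bn
from . import classify as cl
from . import cohort as co
from . import plv as pl
from . import preprocess as pp
from . import spectra as sp
from .stimuli import CONDITIONS, DEFAULT_VOWELS, make_bimodal_set

__all__ = ["RunConfig", "RunResult", "run_pipeline", "demo_config", "subject_tables"]

log = logging.getLogger("bimodalffr")


@dataclass
class RunConfig:
    n_subjects: int = 18
    trials_per_polarity: int = 1000
    conditions: tuple[str, ...] = CONDITIONS
    plv_conditions: tuple[str, ...] = ("Voc", "Voc+750")
    seed: int | None = 0
    classifier_iterations: int = 1000
    words_per_step: int = 4
    output_root: str = "results/pipeline"
    cohort: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output location is
        excluded: two runs differing only in destination are the same run)."""
        d = asdict(self)
        d.pop("output_root", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(output_root: str = "results/demo", seed: int = 0) -> RunConfig:
    """Desk-scale demonstration: 6 subjects, 200 trials per polarity."""
    return RunConfig(
        n_subjects=6,
        trials_per_polarity=200,
        classifier_iterations=200,
        seed=seed,
        output_root=output_root,
    )


@dataclass
class RunResult:
    config: RunConfig
    amplitudes: pd.DataFrame  # subject, vowel, condition, component, amplitude
    plv_table: pd.DataFrame  # subject, vowel, condition, component, plv, floor
    classification: dict  # condition -> ClassifierRun (+ "null", "p_vs_null")
    behavior: pd.DataFrame  # subject, condition, snr50
    records: list  # BenefitRecord
    regression: bn.RegressionResult
    manifest: dict


def subject_tables(
    profile: co.SubjectProfile,
    stimuli: list,
    conditions: tuple[str, ...],
    plv_conditions: tuple[str, ...],
    n_per_polarity: int,
) -> tuple[list[dict], list[dict], dict, dict]:
    """Simulate, preprocess and measure one subject.

    Returns (amplitude rows, PLV rows, {condition: {vowel: FFR spectrum}},
    {condition: {vowel: PLV spectrum}}); the FFR amplitude spectra are the
    polarity-A averages used for decoding.
    """
    amp_rows, plv_rows = [], []
    spectra_by_cond: dict[str, dict[str, sp.FFRSpectrum]] = {}
    plv_by_cond: dict[str, dict[str, pl.PLVSpectrum]] = {}
    for stim in stimuli:
        if stim.condition not in conditions:
            continue
        eeg = co.simulate_trials(stim, profile, n_per_polarity)
        cleaned = pp.clean(pp.epoch(pp.bandpass(eeg)))
        avg_a = pp.average(cleaned, "A")
        spec = sp.ffr_spectrum(
            avg_a, source=(stim.vowel.label, stim.condition, profile.subject_id, "A")
        )
        spectra_by_cond.setdefault(stim.condition, {})[stim.vowel.label] = spec
        for comp, freq in (("f0", 130.0), ("F1", stim.vowel.f1)):
            ca = sp.component_amplitude(spec, freq)
            amp_rows.append(
                dict(
                    subject=profile.subject_id,
                    vowel=stim.vowel.label,
                    condition=stim.condition,
                    component=comp,
                    frequency_hz=freq,
                    bin_hz=ca.bin_hz,
                    amplitude_uv=ca.amplitude,
                )
            )
        if stim.condition in plv_conditions:
            spg_a = pl.plv(cleaned, "A", t_range_ms=(150.0, 250.0))
            spg_b = pl.plv(cleaned, "B", t_range_ms=(150.0, 250.0))
            floor = pl.noise_floor(cleaned)
            spectrum = pl.plv_spectrum(spg_a, spg_b, floor=floor)
            plv_by_cond.setdefault(stim.condition, {})[stim.vowel.label] = spectrum
            for comp, freq in (("f0", 130.0), ("F1", stim.vowel.f1)):
                plv_rows.append(
                    dict(
                        subject=profile.subject_id,
                        vowel=stim.vowel.label,
                        condition=stim.condition,
                        component=comp,
                        frequency_hz=freq,
                        plv=spectrum.at(freq),
                        noise_floor=spectrum.floor_at(freq),
                    )
                )
    return amp_rows, plv_rows, spectra_by_cond, plv_by_cond


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write tidy outputs under the output root."""
    t0 = time.time()
    out = Path(config.output_root)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    log.info("stage stimuli: synthesizing bimodal set")
    stimuli = make_bimodal_set(seed=rng_seed)
    log.info("stage cohort: %d subjects", config.n_subjects)
    cohort_kwargs = dict(config.cohort)
    cohort_kwargs.setdefault("words_per_step", config.words_per_step)
    cohort_cfg = co.CohortConfig(**cohort_kwargs)
    profiles = co.make_cohort(config.n_subjects, seed=rng_seed, config=cohort_cfg)

    amp_rows, plv_rows = [], []
    spectra_all: dict[str, dict[int, dict[str, sp.FFRSpectrum]]] = {}
    plv_all: dict[int, dict[str, dict[str, pl.PLVSpectrum]]] = {}
    for prof in profiles:
        log.info("stage eeg+measures: subject %d", prof.subject_id)
        a_rows, p_rows, spec_by_cond, plv_by_cond = subject_tables(
            prof, stimuli, config.conditions, config.plv_conditions,
            config.trials_per_polarity,
        )
        amp_rows.extend(a_rows)
        plv_rows.extend(p_rows)
        for cond, by_vowel in spec_by_cond.items():
            spectra_all.setdefault(cond, {})[prof.subject_id] = by_vowel
        plv_all[prof.subject_id] = plv_by_cond
    amplitudes = pd.DataFrame(amp_rows)
    plv_table = pd.DataFrame(plv_rows)

    log.info("stage classification: %d iterations", config.classifier_iterations)
    classification = {}
    for ci, cond in enumerate(config.conditions):
        feats = _features_for_condition(spectra_all[cond])
        classification[cond] = cl.cv_iterate(
            feats, n_iter=config.classifier_iterations, seed=rng_seed * 100 + ci
        )
    rich = config.conditions[-1]
    null = cl.null_run(
        _features_for_condition(spectra_all[rich]),
        n_iter=config.classifier_iterations,
        seed=rng_seed * 100 + 57,
    )
    classification["null"] = null
    classification["p_vs_null"] = {
        cond: cl.empirical_p(classification[cond].accuracies, null.accuracies)
        for cond in config.conditions
    }

    log.info("stage behavior: scoring SNR-50")
    beh_rows = []
    thresholds: dict[int, dict[str, bn.SNRThreshold]] = {}
    for prof in profiles:
        thresholds[prof.subject_id] = {}
        for cond in config.conditions:
            run = co.simulate_behavior(prof, cond, config.words_per_step)
            thr = bn.snr50(run)
            thresholds[prof.subject_id][cond] = thr
            beh_rows.append(
                dict(subject=prof.subject_id, condition=cond, snr50_db=thr.threshold)
            )
    behavior = pd.DataFrame(beh_rows)

    log.info("stage regression: neural -> perceptual benefit")
    records = []
    for prof in profiles:
        f0b, f1b = pl.neural_benefit(plv_all[prof.subject_id])
        records.append(
            pl.BenefitRecord(
                subject=prof.subject_id,
                f0_benefit=f0b,
                f1_benefit=f1b,
                behavioral_benefit=bn.perceptual_benefit(thresholds[prof.subject_id]),
            )
        )
    regression = bn.regress_benefit(records)

    manifest = _write_outputs(
        out, config, amplitudes, plv_table, classification, behavior, records, regression
    )
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    log.info("pipeline complete in %.1f s", manifest["elapsed_s"])
    return RunResult(
        config, amplitudes, plv_table, classification, behavior, records, regression,
        manifest,
    )


def _features_for_condition(by_subject: dict[int, dict[str, sp.FFRSpectrum]]) -> cl.FeatureSet:
    rows, labels, subjects = [], [], []
    for sid, by_vowel in sorted(by_subject.items()):
        for vowel, spec in sorted(by_vowel.items()):
            rows.append(spec.amplitudes)
            labels.append(vowel)
            subjects.append(sid)
    return cl.FeatureSet(np.array(rows), np.array(labels), np.array(subjects))


def _write_outputs(out, config, amplitudes, plv_table, classification, behavior,
                   records, regression) -> dict:
    files = {}

    def save(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False)
        files[name] = str(path)

    save(amplitudes, "ffr_component_amplitudes.csv")
    if len(plv_table):
        save(plv_table, "plv_components.csv")
    save(behavior, "behavior_snr50.csv")
    acc_rows = []
    for cond, run in classification.items():
        if not isinstance(run, cl.ClassifierRun):
            continue
        for it, acc in enumerate(run.accuracies):
            acc_rows.append(dict(condition=cond, iteration=it, accuracy=acc))
    save(pd.DataFrame(acc_rows), "classification_accuracies.csv")
    rec = pd.DataFrame(
        [
            dict(
                subject=r.subject,
                f0_benefit=r.f0_benefit,
                f1_benefit=r.f1_benefit,
                behavioral_benefit_db=r.behavioral_benefit,
            )
            for r in records
        ]
    )
    save(rec, "benefit_records.csv")
    summary = {
        "config_hash": config.config_hash(),
        "n_subjects": config.n_subjects,
        "regression": {
            "r2": regression.r2,
            "r2_adj": regression.r2_adj,
            "f": regression.f_stat,
            "f_p": regression.f_pvalue,
            "df": list(regression.df),
            "vif": regression.vif.to_dict() if regression.vif is not None else None,
        },
        "p_vs_null": {
            cond: res.p for cond, res in classification.get("p_vs_null", {}).items()
        },
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    files["run_summary.json"] = str(out / "run_summary.json")
    manifest = {
        "config_hash": config.config_hash(),
        "outputs": files,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
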