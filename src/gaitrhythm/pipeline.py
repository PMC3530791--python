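"""Top-level pipeline: simulate → detect → profile → norms → classify → sync.

Ties every stage together on a simulated cohort, logging each cut-off and
every excluded hour, and writes per-patient reports plus a cohort summary.
Fixed configuration and seed reproduce the report byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import detect, hourly, io, norms as norms_mod, simulate
from .classify import Category, classify_patient, label_hours, recover_planted
from .diary import cohort_summary, subjective_off_hours, synchronize
from .errors import GaitRhythmError, NoTemplateError
from .io import PipelineConfig

log = logging.getLogger("gaitrhythm")


def detect_profile(trace, config: PipelineConfig):
    """Detect steps on one trace and build its hourly profile.

    Falls back to the canonical synthetic step waveform when the trace is
    too sparse to self-template.
    """
    try:
        template = detect.extract_template(trace, band=config.band)
    except NoTemplateError:
        log.info("%s: no self-template; using canonical step waveform",
                 trace.subject_id)
        template = simulate.canonical_template(trace.sample_interval)
    series = detect.match_steps(
        trace, template,
        min_correlation=config.min_correlation,
        refractory=config.refractory,
    )
    profile = hourly.build_profile(series, max_gap=config.max_gap)
    for h in profile.hours:
        if not h.valid:
            log.debug("%s: hour %02d excluded (%d steps < %d)",
                      trace.subject_id, h.hour, h.n_steps, hourly.MIN_STEPS_PER_HOUR)
    return series, profile


def oracle_equivalence_experiment(seed: int, cadence: float = 110.0,
                                  amplitude: float = 2.78) -> dict:
    """Detection vs a half-peak threshold oracle on a noiseless pulse train.

    On a noiseless, artifact-free walking hour the planted pulses are the
    only signal, so thresholding the magnitude at half the pulse peak and
    taking each region's maximum is an exact independent step finder.
    Template matching must agree with it event for event (within one
    sample) for recall and precision to both reach 1.0.
    """
    plan = simulate.DailyPlan(
        hours=[simulate.HourPlan(60.0, cadence, amplitude, "normal")],
        seed=seed, noise_sd=0.0, artifact_rate=0.0,
    )
    trace, truth = simulate.generate_trace(plan)
    a = detect.magnitude(trace)
    above = a > amplitude / 2.0
    idx = np.flatnonzero(above)
    regions = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    oracle_idx = np.array([r[np.argmax(a[r])] for r in regions])

    series = detect.match_steps(trace, detect.extract_template(trace))
    det_idx = np.round(series.times / trace.sample_interval).astype(int)

    tol = 1  # samples
    matched = sum(np.min(np.abs(det_idx - o)) <= tol for o in oracle_idx)
    recall = matched / oracle_idx.size
    precision = (
        sum(np.min(np.abs(oracle_idx - d)) <= tol for d in det_idx) / det_idx.size
    )
    return {
        "n_oracle_events": int(oracle_idx.size),
        "n_detected_events": int(det_idx.size),
        "recall": float(recall),
        "precision": float(precision),
    }


def recovery_experiment(
    n_off_patients: int,
    n_clean_patients: int,
    seed: int,
    n_hours: int = 24,
    walking_minutes: float = 10.0,
    config: PipelineConfig | None = None,
) -> dict:
    """Plant off hours, run the full method, and score recovery.

    Off patients carry 1-4 off hours planted well beyond each cut-off;
    clean patients walk in-band with tight amplitude variability. Returns
    per-hour off sensitivity/specificity, the share of clean patients
    classified definite gait good, and per-hour cadence/amplitude errors
    against the planted values.
    """
    config = config or PipelineConfig()
    s_off, s_clean = (
        int(x) for x in np.random.SeedSequence(seed).generate_state(2) % (2**31)
    )
    off_cohort = simulate.generate_cohort(
        n_off_patients, 0, seed=s_off, n_hours=n_hours,
        walking_minutes=walking_minutes, id_prefix="off-",
    )
    clean_cohort = simulate.generate_cohort(
        n_clean_patients, 0,
        off_schedule=simulate.OffSchedule(min_off_hours=0, max_off_hours=0,
                                          p_activity_hour=0.0),
        seed=s_clean, n_hours=n_hours, walking_minutes=walking_minutes,
        id_prefix="clean-",
    ) if n_clean_patients else []

    assessments, truths = [], []
    cadence_err, amp_rel_err = [], []
    for rec in off_cohort + clean_cohort:
        _, profile = detect_profile(rec.trace, config)
        labels = label_hours(profile, norms_mod.REFERENCE_CUTOFFS)
        cv = hourly.acceleration_cv(profile, ddof=config.cv_ddof)
        assessments.append(
            classify_patient(labels, cv, norms_mod.REFERENCE_CUTOFFS, rec.subject_id)
        )
        truths.append(rec.truth)
        planted = {
            h: (c, a)
            for h, l, c, a in zip(rec.truth.hours, rec.truth.labels,
                                  rec.truth.cadences, rec.truth.amplitudes)
            if l != "rest"
        }
        for hr in profile.hours:
            if hr.valid and hr.hour in planted:
                c, a = planted[hr.hour]
                cadence_err.append(abs(hr.cadence - c))
                amp_rel_err.append(abs(hr.acceleration - a) / a)

    confusion = recover_planted(assessments, truths)
    n_clean_good = sum(
        a.category is Category.DEFINITE_GAIT_GOOD
        for a in assessments[n_off_patients:]
    )
    return {
        "n_patients": n_off_patients + n_clean_patients,
        "n_hours_scored": len(cadence_err),
        "hour_sensitivity": confusion["hour"]["sensitivity"],
        "hour_specificity": confusion["hour"]["specificity"],
        "patient_confusion": confusion["patient"],
        "n_clean_patients": n_clean_patients,
        "n_clean_definite_good": int(n_clean_good),
        "cadence_max_abs_error": float(np.max(cadence_err)) if cadence_err else float("nan"),
        "cadence_mean_abs_error": float(np.mean(cadence_err)) if cadence_err else float("nan"),
        "amplitude_max_rel_error": float(np.max(amp_rel_err)) if amp_rel_err else float("nan"),
        "amplitude_mean_rel_error": float(np.mean(amp_rel_err)) if amp_rel_err else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis on a simulated cohort and write reports."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = simulate.generate_cohort(
            n_patients=config.n_patients,
            n_controls=config.n_controls,
            seed=config.seed,
            awareness=config.awareness,
            walking_minutes=config.walking_minutes,
            n_hours=config.n_hours,
        )
    except GaitRhythmError as exc:
        raise GaitRhythmError(f"simulate stage failed: {exc}") from exc

    profiles, serieses = {}, {}
    for rec in cohort:
        try:
            series, profile = detect_profile(rec.trace, config)
        except GaitRhythmError as exc:
            raise GaitRhythmError(
                f"detect/profile stage failed on {rec.subject_id}: {exc}"
            ) from exc
        serieses[rec.subject_id], profiles[rec.subject_id] = series, profile

    controls = [r for r in cohort if r.kind == "control"]
    patients = [r for r in cohort if r.kind == "patient"]

    if config.cutoff_source == "reference":
        norms, cutoffs = norms_mod.REFERENCE_NORMS, norms_mod.REFERENCE_CUTOFFS
    else:
        norms = norms_mod.compute_norms(
            [profiles[r.subject_id] for r in controls], cv_ddof=config.cv_ddof
        )
        cutoffs = norms_mod.derive_cutoffs(norms)
    log.info("cut-offs: cadence %.4g-%.4g steps/min, acceleration off <%.4g "
             "m/s2, CV <%.4g", cutoffs.cadence_lo, cutoffs.cadence_hi,
             cutoffs.accel_off, cutoffs.cv_max)
    io.write_norms(norms, cutoffs, out / "norms.yaml")

    patient_reports, sync_results, assessments, truths = [], [], [], []
    for rec in patients:
        profile = profiles[rec.subject_id]
        labels = label_hours(profile, cutoffs)
        cv = hourly.acceleration_cv(profile, ddof=config.cv_ddof)
        asmt = classify_patient(labels, cv, cutoffs, subject_id=rec.subject_id)
        assessments.append(asmt)
        truths.append(rec.truth)
        report = {
            "subject_id": rec.subject_id,
            "category": asmt.category.value,
            "accel_cv": asmt.accel_cv,
            "gait_off_hours": sorted(asmt.gait_off_hours),
            "gait_off_clock": [io.clock_style(h) for h in sorted(asmt.gait_off_hours)],
            "hour_labels": {hl.hour: hl.label.value for hl in asmt.hour_labels},
        }
        if asmt.category in (Category.DEFINITE_GAIT_OFF, Category.DEFINITE_GAIT_GOOD):
            sync = synchronize(
                asmt.gait_off_hours,
                subjective_off_hours(rec.diary),
                patient_id=rec.subject_id,
                tolerance=config.sync_tolerance,
            )
            sync_results.append(sync)
            report["sync"] = {
                "outcome": sync.outcome.value,
                "subjective_off_hours": sorted(sync.subjective_off_hours),
                "matched_hours": sorted(sync.matched_hours),
            }
        else:
            report["sync"] = None  # reserved patients are excluded
        patient_reports.append(report)

    report = {
        "config": {
            "seed": config.seed,
            "cutoff_source": config.cutoff_source,
            "n_patients": config.n_patients,
            "n_controls": config.n_controls,
            "awareness": config.awareness,
            "n_hours": config.n_hours,
        },
        "cutoffs": {
            "cadence_lo": cutoffs.cadence_lo,
            "cadence_hi": cutoffs.cadence_hi,
            "accel_off": cutoffs.accel_off,
            "cv_max": cutoffs.cv_max,
        },
        "patients": patient_reports,
        "cohort_sync": cohort_summary(sync_results) if sync_results else None,
        "recovery": recover_planted(assessments, truths) if assessments else None,
    }
    io.write_report(report, out / "cohort_report.json")
    return report
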