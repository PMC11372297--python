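"""End-to-end orchestration of the per-patient and cohort analysis.

Per patient: SBS96 spectrum -> supervised signature refit -> burst
mixture fit (with the qualifying-burst filter and per-burst refits) ->
polymerase driver call -> above/below-driver partition and TMB. At the
cohort level: above-driver gene recurrence, syn/non-syn driver scores,
clinical counts, TMB group comparison, and (for simulated cohorts) a
recovery report against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bursts import BurstModel, fit_bursts, locate_driver_burst, qualify_bursts
from .cohort import CohortReport, GroupTest, summarize_clinical, tmb_group_compare, tmb_summaries
from .driver import (
    DEFAULT_EXOME_MB,
    DriverCall,
    DriverPartition,
    DriverRules,
    call_driver,
    partition_by_driver,
    summarize_no_driver,
)
from .io_formats import ClinicalAnnotation, MutationRecord, SignatureCatalog
from .recurrence import Background, RecurrenceMatrix, build_recurrence, rank_drivers, score_cohort
from .refit import ExposureEstimate, refit, refit_subsets
from .simulate import CohortSim, ToyGeneModel, TruthSet
from .spectrum import SpectrumVector, build_spectrum, class_fractions


@dataclass
class PatientAnalysis:
    patient_id: str
    spectrum: SpectrumVector
    class_fractions: dict[str, float]
    exposures: ExposureEstimate
    burst_model: BurstModel
    qualifying_bursts: list[int]
    burst_exposures: dict[int, ExposureEstimate]
    driver: DriverCall
    driver_burst: int | None
    driver_in_first_burst: bool | None
    partition: DriverPartition


def analyze_patient(patient_id: str, records: list[MutationRecord],
                    catalog: SignatureCatalog, rules: DriverRules | None = None,
                    exome_mb: float = DEFAULT_EXOME_MB, seed: int = 0,
                    k_max: int = 6) -> PatientAnalysis:
    spectrum = build_spectrum(records)
    exposures = refit(spectrum, catalog)
    model = fit_bursts(records, k_max=k_max, seed=seed)
    qualifying = qualify_bursts(model)
    burst_exp = refit_subsets(records, list(model.assignment), catalog)
    burst_exp = {k: v for k, v in burst_exp.items() if k in qualifying}
    driver = call_driver(records, rules)
    if driver.found:
        comp, highest = locate_driver_burst(model, records, driver.record)
        partition = partition_by_driver(records, driver, exome_mb=exome_mb)
    else:
        comp, highest = None, None
        partition = summarize_no_driver(records, exome_mb=exome_mb)
    return PatientAnalysis(
        patient_id=patient_id, spectrum=spectrum,
        class_fractions=class_fractions(spectrum), exposures=exposures,
        burst_model=model, qualifying_bursts=qualifying,
        burst_exposures=burst_exp, driver=driver, driver_burst=comp,
        driver_in_first_burst=highest, partition=partition,
    )


@dataclass
class CohortAnalysis:
    patients: dict[str, PatientAnalysis]
    recurrence: RecurrenceMatrix
    driver_scores: "object"  # ranked DataFrame from rank_drivers
    clinical_report: CohortReport | None = None
    tmb_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    tmb_group_test: GroupTest | None = None


def analyze_cohort(tables: dict[str, list[MutationRecord]],
                   catalog: SignatureCatalog,
                   gene_lengths: dict[str, int] | None = None,
                   clinical: list[ClinicalAnnotation] | None = None,
                   rules: DriverRules | None = None,
                   exome_mb: float = DEFAULT_EXOME_MB,
                   seed: int = 0) -> CohortAnalysis:
    patients: dict[str, PatientAnalysis] = {}
    for i, (pid, records) in enumerate(sorted(tables.items())):
        patients[pid] = analyze_patient(pid, records, catalog, rules=rules,
                                        exome_mb=exome_mb, seed=seed + i)
    drivers = {pid: pa.driver for pid, pa in patients.items()}
    recurrence = build_recurrence(tables, drivers)
    all_records = [r for recs in tables.values() for r in recs]
    background = Background.from_records(all_records)
    scores = score_cohort(all_records, gene_lengths or {}, background)
    ranked = rank_drivers(scores)

    clinical_report = summarize_clinical(clinical) if clinical else None
    tmb = {pid: pa.partition.tmb_total for pid, pa in patients.items()}
    group_test = None
    summaries = {}
    if clinical:
        genes = {a.patient_id: a.mmr_gene for a in clinical}
        summaries = tmb_summaries(tmb, genes)
        if len(set(genes.values())) == 2:
            group_test = tmb_group_compare(tmb, genes)
    else:
        summaries = tmb_summaries(tmb, {})
    return CohortAnalysis(patients=patients, recurrence=recurrence,
                          driver_scores=ranked, clinical_report=clinical_report,
                          tmb_summary=summaries, tmb_group_test=group_test)


# ---------------------------------------------------------------------------
# Truth recovery (simulated cohorts)
# ---------------------------------------------------------------------------

def recovery_report(analysis: CohortAnalysis, truth: TruthSet) -> dict:
    """Compare pipeline output against the planted ground truth.

    Reports driver-call accuracy, burst-number and burst-center
    recovery, exposure recovery for the dominant signature, and the
    above/below partition error relative to true mutation timing.
    """
    by_pid = {p.patient_id: p for p in truth.patients}
    n = len(truth.patients)
    driver_correct = 0
    k_correct = 0
    center_errors: list[float] = []
    exposure_errors: list[float] = []
    driver_vaf_errors: list[float] = []
    driver_in_first = 0
    n_with_driver = 0
    for pid, pa in analysis.patients.items():
        pt = by_pid[pid]
        true_gene = pt.driver.gene if pt.driver else "none"
        if pa.driver.gene == true_gene:
            driver_correct += 1
        if pt.driver is not None:
            n_with_driver += 1
            if pa.driver.found:
                driver_vaf_errors.append(abs(pa.driver.vaf - pt.driver.vaf_true))
                if pa.driver_in_first_burst:
                    driver_in_first += 1
        true_k = len(pt.bursts)
        if pa.burst_model.K == true_k:
            k_correct += 1
            fitted = np.sort(pa.burst_model.centers)[::-1]
            truth_centers = np.sort([b.vaf_center for b in pt.bursts])[::-1]
            center_errors.extend(np.abs(fitted - truth_centers))
        # exposure recovery: truth exposures are shared across bursts
        true_exp = pt.bursts[0].exposure
        est = pa.exposures.fractions()
        for sig, w in true_exp.items():
            exposure_errors.append(abs(est.get(sig, 0.0) - w))
    return {
        "n_patients": n,
        "driver_call_accuracy": driver_correct / n,
        "n_true_drivers": n_with_driver,
        "driver_in_first_burst_rate": (driver_in_first / n_with_driver
                                       if n_with_driver else None),
        "mean_driver_vaf_error": (float(np.mean(driver_vaf_errors))
                                  if driver_vaf_errors else None),
        "burst_number_accuracy": k_correct / n,
        "mean_burst_center_error": (float(np.mean(center_errors))
                                    if center_errors else None),
        "mean_exposure_error": float(np.mean(exposure_errors)),
    }
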