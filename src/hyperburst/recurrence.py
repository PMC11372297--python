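"""Above-driver gene recurrence and a synonymous/non-synonymous driver score.

Recurrently mutated genes are tallied per patient over non-synonymous
coding SNVs whose VAF is at or above the patient's driving polymerase
mutation (all non-synonymous SNVs for driverless patients), keeping
genes hit in at least a configurable fraction of patients.

The driver score asks whether a gene carries more non-synonymous
mutations than its synonymous count predicts. Counts are modelled as
two Poisson observations: under the null the gene shares the cohort's
non-synonymous-to-synonymous opportunity ratio rho (one free rate),
under the alternative the gene's non-synonymous rate is free. The
likelihood-ratio statistic 2*(l1 - l0) is referred to chi-square with
one degree of freedom. All MLEs are closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .driver import DriverCall
from .io_formats import MutationRecord, NONSYNONYMOUS_EFFECTS

VAF_TIE_TOL = 1e-9


@dataclass
class RecurrenceMatrix:
    """Gene-by-patient counts of above-driver non-synonymous SNVs."""

    counts: pd.DataFrame  # index: gene, columns: patient_id
    min_patients: int

    @property
    def nb_mut_pat(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    @property
    def nb_muts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def filtered(self) -> pd.DataFrame:
        keep = self.nb_mut_pat >= self.min_patients
        df = self.counts.loc[keep].copy()
        df["nb_mut_pat"] = self.nb_mut_pat[keep]
        df["nb_muts"] = self.nb_muts[keep]
        return df.sort_values(["nb_mut_pat", "nb_muts"],
                              ascending=False, kind="stable")


def build_recurrence(per_patient_records: dict[str, list[MutationRecord]],
                     per_patient_driver: dict[str, DriverCall],
                     min_patients: int | None = None,
                     min_fraction: float = 2 / 3) -> RecurrenceMatrix:
    """Tally per-patient above-driver non-synonymous mutation counts.

    ``min_patients`` defaults to ``ceil(min_fraction * n_patients)``
    (e.g. 8 of 12). Patients without a called driver contribute all
    their non-synonymous SNVs. A VAF tied with the driver's counts as
    above.
    """
    missing = set(per_patient_driver) - set(per_patient_records)
    if missing:
        raise ValueError(f"driver call for unknown patient(s): {sorted(missing)}")
    patients = list(per_patient_records)
    if min_patients is None:
        min_patients = math.ceil(min_fraction * len(patients))
    cells: dict[str, dict[str, int]] = {}
    for pid in patients:
        driver = per_patient_driver.get(pid, DriverCall("none", None, None))
        cutoff = driver.vaf if driver.found else None
        for r in per_patient_records[pid]:
            if r.effect not in NONSYNONYMOUS_EFFECTS:
                continue
            if cutoff is not None and r.vaf <= cutoff - VAF_TIE_TOL:
                continue
            cells.setdefault(r.gene, {}).setdefault(pid, 0)
            cells[r.gene][pid] += 1
    genes = sorted(cells)
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"),
                       columns=pd.Index(patients, name="patient_id"), dtype=int)
    for g, per_pat in cells.items():
        for pid, c in per_pat.items():
            mat.loc[g, pid] = c
    # reorder columns deterministically so patient input order is irrelevant
    mat = mat[sorted(patients)]
    return RecurrenceMatrix(counts=mat, min_patients=min_patients)


# ---------------------------------------------------------------------------
# Driver score: Poisson likelihood-ratio test on syn vs non-syn counts
# ---------------------------------------------------------------------------

@dataclass
class Background:
    """Cohort-wide opportunity: expected non-syn per synonymous mutation."""

    rho: float
    total_nonsyn: int = 0
    total_syn: int = 0

    @classmethod
    def from_records(cls, records: list[MutationRecord]) -> "Background":
        n_n = sum(1 for r in records if r.effect in NONSYNONYMOUS_EFFECTS)
        n_s = sum(1 for r in records if r.effect == "synonymous")
        if n_s == 0:
            raise ValueError("no synonymous mutations; background ratio undefined")
        return cls(rho=n_n / n_s, total_nonsyn=n_n, total_syn=n_s)


@dataclass
class DriverScore:
    gene: str
    n_nonsyn: int
    n_syn: int
    coding_length_bp: int
    lrt_statistic: float
    p_value: float


def _pois_ll(k: int, lam: float) -> float:
    """Poisson log-likelihood up to the k!-term (cancels in the LRT);
    0*log(0) treated as 0."""
    if lam <= 0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(lam) - lam


def score_driver_gene(gene: str, n_nonsyn: int, n_syn: int,
                      coding_length_bp: int, background: Background) -> DriverScore:
    """Likelihood-ratio driver score for one gene (closed-form MLEs)."""
    if coding_length_bp <= 0:
        raise ValueError(f"gene {gene}: coding length must be positive")
    if n_nonsyn < 0 or n_syn < 0:
        raise ValueError("negative mutation counts")
    rho = background.rho
    lam0 = (n_syn + n_nonsyn) / (1.0 + rho)
    ll0 = _pois_ll(n_syn, lam0) + _pois_ll(n_nonsyn, rho * lam0)
    ll1 = _pois_ll(n_syn, float(n_syn)) + _pois_ll(n_nonsyn, float(n_nonsyn))
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    if n_syn + n_nonsyn == 0:
        lrt, p = 0.0, 1.0
    else:
        p = float(chi2.sf(lrt, df=1))
    return DriverScore(gene=gene, n_nonsyn=n_nonsyn, n_syn=n_syn,
                       coding_length_bp=coding_length_bp,
                       lrt_statistic=lrt, p_value=p)


def score_cohort(records: list[MutationRecord], gene_lengths: dict[str, int],
                 background: Background | None = None) -> list[DriverScore]:
    """Score every gene present in ``records`` (needs its coding length)."""
    background = background or Background.from_records(records)
    per_gene: dict[str, list[int]] = {}
    for r in records:
        ns = per_gene.setdefault(r.gene, [0, 0])
        ns[0 if r.effect in NONSYNONYMOUS_EFFECTS else 1] += 1
    return [
        score_driver_gene(g, nn, ns, gene_lengths.get(g, 0), background)
        for g, (nn, ns) in sorted(per_gene.items())
    ]


def rank_drivers(scores: list[DriverScore], alpha: float = 0.05,
                 correction: str = "fdr_bh") -> pd.DataFrame:
    """Rank scores (LRT descending, gene name breaking ties) and flag
    significance after multiple-testing correction (Benjamini-Hochberg
    by default)."""
    if not scores:
        return pd.DataFrame(columns=["gene", "n_nonsyn", "n_syn", "lrt",
                                     "p_value", "q_value", "significant"])
    ordered = sorted(scores, key=lambda s: (-s.lrt_statistic, s.gene))
    pvals = np.array([s.p_value for s in ordered])
    reject, qvals, *_ = multipletests(pvals, alpha=alpha, method=correction)
    return pd.DataFrame({
        "gene": [s.gene for s in ordered],
        "n_nonsyn": [s.n_nonsyn for s in ordered],
        "n_syn": [s.n_syn for s in ordered],
        "lrt": [s.lrt_statistic for s in ordered],
        "p_value": pvals,
        "q_value": qvals,
        "significant": reject,
    })
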