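"""Cohort-level descriptive statistics and group comparisons.

Clinical counts follow immunohistochemistry reporting practice: stains
scored NA drop out of the denominator, while prevalence quoted "of all
samples" keeps the full cohort as denominator (both PDL1 denominators
are reported). The TMB comparison between MMR-gene groups uses the
two-sided Wilcoxon-Mann-Whitney rank-sum test, exact by full
enumeration for combined n <= 20 and by normal approximation with
continuity and tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .io_formats import ClinicalAnnotation

GIANT_CELL_PHRASE = "giant multi-nucleated cells"
EXACT_MAX_N = 20


@dataclass
class GroupTest:
    statistic: float
    p_value: float
    method: str


@dataclass
class CohortReport:
    counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    tmb_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    group_test: GroupTest | None = None

    def fraction(self, name: str) -> float | None:
        num, den = self.counts[name]
        return num / den if den else None


def summarize_clinical(annotations: list[ClinicalAnnotation]) -> CohortReport:
    """Descriptive counts over the clinical annotation table.

    Each entry is (numerator, denominator); denominators exclude NA for
    stain-based counts and cover all samples for cohort-wide ones.
    """
    n = len(annotations)

    def stained(values, positive) -> tuple[int, int]:
        known = [v for v in values if v is not None]
        return sum(1 for v in known if positive(v)), len(known)

    atrx = stained([a.atrx_loss for a in annotations], lambda v: v == 1)
    p53 = stained([a.p53_staining for a in annotations], lambda v: v == 1)
    pdl1_st = stained([a.pdl1_score for a in annotations], lambda v: v >= 1)
    cd8 = stained([a.cd8_infiltrate for a in annotations], lambda v: v == 1)
    report = CohortReport(counts={
        "atrx_loss": atrx,
        "p53_positive": p53,
        "pdl1_positive_of_stained": pdl1_st,
        "pdl1_positive_of_all": (pdl1_st[0], n),
        "cd8_infiltrate": cd8,
        "giant_cell_histology": (
            sum(1 for a in annotations if GIANT_CELL_PHRASE in a.histology_text), n),
        "mmr_pms2": (sum(1 for a in annotations if a.mmr_gene == "PMS2"), n),
        "mmr_msh6": (sum(1 for a in annotations if a.mmr_gene == "MSH6"), n),
    })
    return report


def _median(values: list[float]) -> float:
    return float(np.median(values))


def tmb_summaries(tmb_by_patient: dict[str, float],
                  gene_by_patient: dict[str, str]) -> dict[str, dict[str, float]]:
    """Median/min/max TMB overall and per MMR gene group."""
    out = {}
    groups = {"overall": list(tmb_by_patient.values())}
    for pid, tmb in tmb_by_patient.items():
        groups.setdefault(gene_by_patient.get(pid, "unknown"), []).append(tmb)
    for name, vals in groups.items():
        if vals:
            out[name] = {"median": _median(vals),
                         "min": float(min(vals)), "max": float(max(vals))}
    return out


def exact_rank_sum_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Wilcoxon-Mann-Whitney p by full enumeration.

    Midranks handle ties; the two-sided p-value is the probability,
    over all equally likely assignments of the pooled ranks to the two
    groups, of a U statistic at least as far from its mean n1*n2/2 as
    observed.
    """
    n1, n2 = len(x), len(y)
    pooled = np.array(list(x) + list(y), dtype=float)
    ranks = rankdata(pooled)  # midranks
    mean_u = n1 * n2 / 2.0
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    obs_dev = abs(obs_u - mean_u)
    rank_offset = n1 * (n1 + 1) / 2.0
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - rank_offset
        if abs(u - mean_u) >= obs_dev - 1e-12:
            hits += 1
    return hits / comb(n1 + n2, n1)


def tmb_group_compare(tmb_by_patient: dict[str, float],
                      group_by_patient: dict[str, str]) -> GroupTest:
    """Compare TMB between the two MMR-gene groups (two-sided)."""
    groups: dict[str, list[float]] = {}
    for pid, tmb in tmb_by_patient.items():
        groups.setdefault(group_by_patient[pid], []).append(tmb)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(groups)}")
    (ga, x), (gb, y) = sorted(groups.items())
    if not x or not y:
        raise ValueError("both groups must be non-empty")
    u_stat = float(mannwhitneyu(x, y, alternative="two-sided",
                                method="asymptotic").statistic)
    if len(x) + len(y) <= EXACT_MAX_N:
        p = exact_rank_sum_p(x, y)
        method = "rank-sum exact enumeration"
    else:
        p = float(mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic").pvalue)
        method = "rank-sum normal approximation"
    return GroupTest(statistic=u_stat, p_value=p, method=method)
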