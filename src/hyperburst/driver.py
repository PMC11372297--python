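"""POLE/POLD1 driver calling, VAF partitioning and mutation burden.

In MMR-deficient tumors a somatic proofreading (exonuclease) domain
mutation in *POLE* or *POLD1* is the presumed co-driver of the
ultra-hypermutated phenotype. Under the standard assumptions (no
copy-number change at the locus, no strong clonal selection), a
mutation's VAF orders it in time relative to the driver: higher VAF
means earlier. This module calls the candidate driver from editable
curation rules (a protein-change whitelist plus exonuclease-domain
residue intervals), splits the remaining coding SNVs into
before-driver (VAF above) and after-driver (VAF below) sets, and
computes tumor mutation burden (coding SNV per Mb of captured exome)
and the ultra-hypermutation flag (TMB >= 100/Mb).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import yaml

from .io_formats import MutationRecord

logger = logging.getLogger(__name__)

# Exome size of the capture design in Mb. Not a measured constant of this
# package: a typical clinical research exome footprint, consistent with
# cohort TMB figures of ~174/Mb at ~9400 coding SNVs. Override in config
# when the real interval size is known.
DEFAULT_EXOME_MB = 54.0
ULTRA_TMB_THRESHOLD = 100.0
DRIVER_VAF_WARN = 0.31

_PCHANGE_RE = re.compile(r"^[A-Z](\d+)(?:[A-Z*]|fs.*|del.*|dup.*)?$")


@dataclass
class DriverRules:
    """Editable curation of qualifying polymerase proofreading mutations.

    Defaults are shipped curation (recurrent validated hotspots and the
    commonly quoted exonuclease-domain residue ranges), not cohort data;
    edit per study.
    """

    whitelist: dict[str, set[str]] = field(default_factory=lambda: {
        "POLE": {"P286R", "V411L", "S459F", "L424V"},
        "POLD1": set(),
    })
    exonuclease_domains: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "POLE": (268, 471),
        "POLD1": (304, 533),
    })

    @classmethod
    def from_yaml(cls, path) -> "DriverRules":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rules = cls()
        for gene, muts in (raw.get("whitelist") or {}).items():
            rules.whitelist[gene] = set(muts or [])
        for gene, iv in (raw.get("exonuclease_domains") or {}).items():
            rules.exonuclease_domains[gene] = (int(iv[0]), int(iv[1]))
        return rules

    def matches(self, record: MutationRecord) -> bool:
        if record.gene not in self.exonuclease_domains and record.gene not in self.whitelist:
            return False
        pc = record.protein_change
        if pc and pc in self.whitelist.get(record.gene, ()):
            return True
        if pc and record.gene in self.exonuclease_domains:
            m = _PCHANGE_RE.match(pc)
            if m:
                lo, hi = self.exonuclease_domains[record.gene]
                return lo <= int(m.group(1)) <= hi
        return False


@dataclass
class DriverCall:
    """The selected candidate driving polymerase mutation (or none)."""

    gene: str  # "POLE", "POLD1" or "none"
    record: MutationRecord | None
    vaf: float | None
    rationale: str | None = None  # "whitelist" | "exonuclease_domain" | "manual"

    @property
    def found(self) -> bool:
        return self.gene != "none"


@dataclass
class DriverPartition:
    """Counts and burdens split at the driver VAF.

    ``fold`` is the after/before ratio n_below / n_above; ``ultra`` is
    the conventional ultra-hypermutation call (TMB >= 100 coding
    SNV/Mb), ``ultra_above`` the same applied only to the above-driver
    (pre-driver) mutations.
    """

    n_total: int
    tmb_total: float
    ultra: bool
    n_above: int | None = None
    n_below: int | None = None
    tmb_above: float | None = None
    tmb_below: float | None = None
    fold: float | None = None
    ultra_above: bool | None = None

    def summary(self) -> str:
        lines = [f"coding SNVs: {self.n_total}  TMB: {self.tmb_total:.1f}/Mb  "
                 f"ultra-hypermutated: {self.ultra}"]
        if self.n_above is not None:
            lines.append(
                f"above driver VAF: {self.n_above} ({self.tmb_above:.1f}/Mb)  "
                f"below: {self.n_below} ({self.tmb_below:.1f}/Mb)  "
                f"fold after/before: {self.fold:.2f}"
            )
        return "\n".join(lines)


def call_driver(records: list[MutationRecord],
                rules: DriverRules | None = None) -> DriverCall:
    """Select the candidate driving polymerase mutation.

    Among POLE/POLD1 records matching the rules, the one with the
    highest VAF is chosen (proofreading drivers are expected clonal,
    VAF > 0.31 and typically near 0.40; lower values trigger a
    warning). No match yields ``gene == "none"``.
    """
    rules = rules or DriverRules()
    hits = [r for r in records if gene_is_polymerase(r.gene) and rules.matches(r)]
    if not hits:
        return DriverCall(gene="none", record=None, vaf=None)
    keys = [(r.chrom, r.pos, r.ref, r.alt) for r in hits]
    if len(set(keys)) != len(keys):
        raise ValueError("conflicting duplicate polymerase driver records")
    best = max(hits, key=lambda r: r.vaf)
    rationale = ("whitelist"
                 if best.protein_change in rules.whitelist.get(best.gene, ())
                 else "exonuclease_domain")
    if best.vaf <= DRIVER_VAF_WARN:
        logger.warning(
            "selected %s driver VAF %.3f <= %.2f; proofreading drivers are "
            "usually clonal", best.gene, best.vaf, DRIVER_VAF_WARN,
        )
    return DriverCall(gene=best.gene, record=best, vaf=best.vaf, rationale=rationale)


def gene_is_polymerase(gene: str) -> bool:
    return gene in ("POLE", "POLD1")


def partition_by_driver(records: list[MutationRecord], driver: DriverCall,
                        exome_mb: float = DEFAULT_EXOME_MB) -> DriverPartition:
    """Split coding SNVs at the driver VAF (driver itself on neither side).

    A record whose VAF equals the driver's (tolerance 1e-9) counts as
    above (i.e. not later than the driver).
    """
    if not driver.found:
        raise ValueError("no driver called; use summarize_no_driver instead")
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    n_total = len(records)
    others = [r for r in records if r is not driver.record]
    if len(others) == n_total:
        # driver passed by value: drop the first site-identical record
        key = (driver.record.chrom, driver.record.pos,
               driver.record.ref, driver.record.alt)
        for i, r in enumerate(records):
            if (r.chrom, r.pos, r.ref, r.alt) == key:
                others = records[:i] + records[i + 1:]
                break
        else:
            raise ValueError("driver record is not among the records")
    n_above = sum(1 for r in others if r.vaf > driver.vaf - 1e-9)
    n_below = len(others) - n_above
    tmb_total = n_total / exome_mb
    fold = n_below / n_above if n_above > 0 else math.inf
    return DriverPartition(
        n_total=n_total,
        tmb_total=tmb_total,
        ultra=tmb_total >= ULTRA_TMB_THRESHOLD,
        n_above=n_above,
        n_below=n_below,
        tmb_above=n_above / exome_mb,
        tmb_below=n_below / exome_mb,
        fold=fold,
        ultra_above=n_above / exome_mb >= ULTRA_TMB_THRESHOLD,
    )


def summarize_no_driver(records: list[MutationRecord],
                        exome_mb: float = DEFAULT_EXOME_MB) -> DriverPartition:
    """Burden summary for a tumor without a called polymerase driver."""
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    tmb = len(records) / exome_mb
    return DriverPartition(n_total=len(records), tmb_total=tmb,
                           ultra=tmb >= ULTRA_TMB_THRESHOLD)
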