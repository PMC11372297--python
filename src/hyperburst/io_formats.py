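"""Readers and writers for the on-disk artifacts.

All tables are plain TSV. Mutation tables follow a MAF-like dialect
(1-based coordinates, pre-annotated gene / coding effect / trinucleotide
context, raw read counts); signature catalogs follow the COSMIC SBS96
dialect (a ``Type`` column with labels like ``A[C>A]A``); the clinical
table mirrors the cohort annotation sheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .channels import BASES, CHANNEL_INDEX, CHANNEL_LABELS, N_CHANNELS

logger = logging.getLogger(__name__)

EFFECTS = ("synonymous", "missense", "nonsense", "splice", "other_coding")
NONSYNONYMOUS_EFFECTS = frozenset(EFFECTS) - {"synonymous"}

MUTATION_COLUMNS = (
    "patient_id", "chrom", "pos", "ref", "alt", "gene", "effect",
    "context3", "alt_reads", "depth",
)


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(slots=True)
class MutationRecord:
    """One somatic single-nucleotide variant with its read support."""

    patient_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    context3: str
    alt_reads: int
    depth: int
    vaf: float
    protein_change: str | None = None

    def validate(self, row: int | None = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(f"non-SNV alleles {self.ref}>{self.alt}{where}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}){where}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}{where}")
        if len(self.context3) != 3 or self.context3[1] != self.ref:
            raise ValidationError(
                f"context3 {self.context3!r} middle base != ref {self.ref}{where}"
            )
        if any(b not in BASES for b in self.context3):
            raise ValidationError(f"context3 {self.context3!r} not over ACGT{where}")
        if self.alt_reads < 0 or self.depth < self.alt_reads:
            raise ValidationError(
                f"require 0 <= alt_reads <= depth, got {self.alt_reads}/{self.depth}{where}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf {self.vaf} outside [0,1]{where}")
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 1e-6:
            raise ValidationError(
                f"vaf {self.vaf} disagrees with alt_reads/depth "
                f"{self.alt_reads}/{self.depth}{where}"
            )


@dataclass
class MutationTable:
    """Validated SNV records plus the count of excluded non-SNV rows."""

    records: list[MutationRecord]
    excluded_non_snv: int = 0

    def __iter__(self) -> Iterator[MutationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES


def read_mutation_table(path, dialect_config: dict | None = None) -> MutationTable:
    """Read a MAF-like TSV of somatic SNVs.

    ``dialect_config`` maps the canonical column names to the file's
    column names (identity by default). Rows whose ref or alt allele is
    not a single A/C/G/T base (indels, MNVs) are excluded and counted.
    A ``vaf`` column, when present, is cross-checked against
    alt_reads/depth; disagreement beyond 1e-6 is an error.
    """
    colmap = {c: c for c in MUTATION_COLUMNS}
    colmap["vaf"] = "vaf"
    colmap["protein_change"] = "protein_change"
    if dialect_config:
        colmap.update(dialect_config)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for canon in MUTATION_COLUMNS:
        if colmap[canon] not in df.columns:
            raise FormatError(f"missing required column {colmap[canon]!r} in {path}")
    has_vaf = colmap["vaf"] in df.columns
    has_pchange = colmap["protein_change"] in df.columns

    cols = {c: df[colmap[c]].tolist() for c in MUTATION_COLUMNS}
    vaf_col = df[colmap["vaf"]].tolist() if has_vaf else None
    pchange_col = df[colmap["protein_change"]].tolist() if has_pchange else None

    records: list[MutationRecord] = []
    excluded = 0
    for j in range(len(df)):
        rownum = j + 2  # 1-based, after the header line
        ref, alt = str(cols["ref"][j]), str(cols["alt"][j])
        if not _is_snv(ref, alt):
            excluded += 1
            continue
        alt_reads = int(cols["alt_reads"][j])
        depth = int(cols["depth"][j])
        raw_vaf = vaf_col[j] if has_vaf else None
        if raw_vaf is not None and not pd.isna(raw_vaf) and str(raw_vaf) != "":
            vaf = float(raw_vaf)
        elif depth > 0:
            vaf = alt_reads / depth
        else:
            raise ValidationError(f"row {rownum}: no vaf and zero depth")
        pchange = None
        if pchange_col is not None:
            raw = pchange_col[j]
            pchange = None if pd.isna(raw) or raw == "" else str(raw)
        rec = MutationRecord(
            patient_id=str(cols["patient_id"][j]),
            chrom=str(cols["chrom"][j]),
            pos=int(cols["pos"][j]),
            ref=ref,
            alt=alt,
            gene=str(cols["gene"][j]),
            effect=str(cols["effect"][j]),
            context3=str(cols["context3"][j]),
            alt_reads=alt_reads,
            depth=depth,
            vaf=vaf,
            protein_change=pchange,
        )
        rec.validate(row=rownum)
        records.append(rec)
    return MutationTable(records=records, excluded_non_snv=excluded)


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    """Write records as TSV; inverse of :func:`read_mutation_table`."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id, "chrom": r.chrom, "pos": r.pos,
                "ref": r.ref, "alt": r.alt, "gene": r.gene, "effect": r.effect,
                "context3": r.context3, "alt_reads": r.alt_reads, "depth": r.depth,
                "vaf": f"{r.vaf:.10g}",
                "protein_change": r.protein_change or "",
            }
        )
    pd.DataFrame(rows, columns=list(MUTATION_COLUMNS) + ["vaf", "protein_change"]).to_csv(
        path, sep="\t", index=False
    )


def records_to_frame(records: Sequence[MutationRecord]) -> pd.DataFrame:
    """Columnar view of a record list (for vectorized pipeline stages)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "gene": [r.gene for r in records],
            "effect": [r.effect for r in records],
            "alt_reads": np.array([r.alt_reads for r in records], dtype=np.int64),
            "depth": np.array([r.depth for r in records], dtype=np.int64),
            "vaf": np.array([r.vaf for r in records], dtype=float),
        }
    )


# ---------------------------------------------------------------------------
# Signature catalogs
# ---------------------------------------------------------------------------

@dataclass
class SignatureCatalog:
    """A fixed set of SBS96 signatures (columns sum to one)."""

    signature_names: list[str]
    weights: np.ndarray  # (96, S)
    channel_labels: tuple[str, ...] = field(default=CHANNEL_LABELS)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (N_CHANNELS, len(self.signature_names)):
            raise FormatError(
                f"weights shape {self.weights.shape} != (96, {len(self.signature_names)})"
            )
        if (self.weights < 0).any():
            raise ValidationError("negative signature weight")
        sums = self.weights.sum(axis=0)
        off = np.abs(sums - 1.0)
        if (off > 1e-3).any():
            bad = self.signature_names[int(np.argmax(off))]
            raise ValidationError(
                f"signature {bad} column sums to {sums[np.argmax(off)]:.4f}, not 1"
            )
        self.weights = self.weights / sums  # renormalize within tolerance

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    def column(self, name: str) -> np.ndarray:
        return self.weights[:, self.signature_names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.signature_names.index(n) for n in names]
        return SignatureCatalog(list(names), self.weights[:, idx])


def read_signature_catalog(path) -> SignatureCatalog:
    """Read a COSMIC-dialect SBS96 TSV (``Type`` column + one column per
    signature); rows are reordered to the canonical channel order."""
    df = pd.read_csv(path, sep="\t", comment="#")
    label_col = df.columns[0]
    if len(df) != N_CHANNELS:
        raise FormatError(f"expected 96 channel rows, found {len(df)}")
    labels = df[label_col].astype(str)
    unknown = [l for l in labels if l not in CHANNEL_INDEX]
    if unknown:
        raise FormatError(f"unknown channel label {unknown[0]!r}")
    if len(set(labels)) != N_CHANNELS:
        raise FormatError("duplicate channel labels")
    order = np.argsort([CHANNEL_INDEX[l] for l in labels], kind="stable")
    mat = df.drop(columns=[label_col]).to_numpy(dtype=float)[order]
    return SignatureCatalog(list(df.columns[1:]), mat)


def write_signature_catalog(catalog: SignatureCatalog, path) -> None:
    df = pd.DataFrame(catalog.weights, columns=catalog.signature_names)
    df.insert(0, "Type", list(CHANNEL_LABELS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical annotations
# ---------------------------------------------------------------------------

MMR_GENES = ("PMS2", "MSH6")


@dataclass(slots=True)
class ClinicalAnnotation:
    """One patient's clinical / immunohistochemistry annotation.

    Binary stains are 0/1 with ``None`` for not-available; the PDL1
    score is graded 0 (<5% positive tumor cells), 1 (<50%), 2 (>50%).
    """

    patient_id: str
    mmr_gene: str
    histology_text: str
    atrx_loss: int | None
    p53_staining: int | None
    pdl1_score: int | None
    cd8_infiltrate: int | None

    def validate(self) -> None:
        if self.mmr_gene not in MMR_GENES:
            raise ValidationError(f"unknown MMR gene {self.mmr_gene!r}")
        for name, val, allowed in (
            ("atrx_loss", self.atrx_loss, (0, 1)),
            ("p53_staining", self.p53_staining, (0, 1)),
            ("pdl1_score", self.pdl1_score, (0, 1, 2)),
            ("cd8_infiltrate", self.cd8_infiltrate, (0, 1)),
        ):
            if val is not None and val not in allowed:
                raise ValidationError(f"{name} value {val!r} not in {allowed}/NA")


def _na_int(token) -> int | None:
    if pd.isna(token) or str(token).strip() in ("NA", ""):
        return None
    return int(token)


def read_clinical_table(path) -> list[ClinicalAnnotation]:
    """Read the clinical annotation TSV; the ``NA`` token means missing."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.empty:
        logger.warning("clinical table %s is empty", path)
        return []
    out: list[ClinicalAnnotation] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        ann = ClinicalAnnotation(
            patient_id=str(row["patient_id"]),
            mmr_gene=str(row["mmr_gene"]),
            histology_text=str(row["histology"]),
            atrx_loss=_na_int(row["atrx_loss"]),
            p53_staining=_na_int(row["p53_staining"]),
            pdl1_score=_na_int(row["pdl1_score"]),
            cd8_infiltrate=_na_int(row["cd8_infiltrate"]),
        )
        ann.validate()
        if ann.patient_id in seen:
            raise ValidationError(f"duplicate patient_id {ann.patient_id}")
        seen.add(ann.patient_id)
        out.append(ann)
    return out


def cohort_fixture_path() -> Path:
    """Path to the packaged 12-patient clinical annotation fixture."""
    return Path(__file__).parent / "fixtures" / "table1.tsv"
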