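"""Synthetic cohort generator with planted ground truth.

Emulates the data model of an ultra-hypermutated MMR-deficient glioma
exome cohort: each tumor carries one or more VAF-clustered mutation
bursts, each burst drawing its trinucleotide channels from a known
mixture of signature catalog columns; most tumors carry a planted
clonal polymerase proofreading driver (POLE or POLD1, VAF 0.31-0.45)
sitting in the highest-VAF burst; a handful of driver genes (TP53,
NF1, SETD2, ...) are planted recurrently at above-driver VAF. Read
depth is Poisson (default mean 150, truncated at 20) and observed alt
counts are binomial, so observed VAFs carry realistic counting noise.
Everything is seeded and byte-reproducible; the planted configuration
is emitted as a truth file for recovery tests.

The bundled signature catalog is synthetic: columns are constructed
programmatically with COSMIC-style names (SBS1, SBS5, SBS10a/b, SBS14,
SBS15, SBS20) and qualitatively similar channel concentrations, so no
third-party matrix ships with the package. Real COSMIC TSVs can be
used instead via `read_signature_catalog`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .channels import N_CHANNELS, classify_channel, decode_channel, revcomp
from .io_formats import (
    ClinicalAnnotation,
    MutationRecord,
    SignatureCatalog,
    write_mutation_table,
)

DEFAULT_DEPTH_MEAN = 150.0
DEPTH_FLOOR = 20
DEFAULT_EXOME_MB = 54.0
DEFAULT_SYN_FRACTION = 0.25


# ---------------------------------------------------------------------------
# Synthetic signature catalog
# ---------------------------------------------------------------------------

# peak channels per synthetic signature: (substitution class block 0-5,
# list of 0-15 context slots) -- contexts are 5'*4 + 3' over A,C,G,T
_PEAK_PLAN = {
    # C>T at NpCpG sites, clock-like deamination flavor
    "SBS1": [(2, [2, 6, 10, 14])],
    # broad, featureless background
    "SBS5": [],
    # C>A peaked at TpCpT, proofreading-deficiency flavor
    "SBS10a": [(0, [15, 13]), (0, [12])],
    # C>T peaked at TpCpG/TpCpT
    "SBS10b": [(2, [14, 15]), (2, [12])],
    # mixed C>A at NpCpT with C>T spread, POLE+MMR flavor
    "SBS14": [(0, [3, 7, 11]), (2, [1, 5])],
    # C>T at GpCpN with C>G shoulder, MMR-deficiency flavor
    "SBS15": [(2, [8, 9, 10, 11]), (1, [9])],
    # C>A at CpCpN with C>T at ApCpN, POLD1+MMR flavor
    "SBS20": [(0, [4, 5, 6]), (2, [0, 3])],
}


def synthetic_catalog(n_nuisance: int = 4, seed: int = 7) -> SignatureCatalog:
    """Deterministic synthetic SBS96 catalog (not COSMIC data).

    Each named column puts ~75% of its mass on a few designated peak
    channels over a small uniform background; nuisance columns (NSx)
    are seeded random sparse profiles, so supervised refits must
    actively reject them.
    """
    rng = np.random.default_rng(seed)
    names, cols = [], []
    for name, peaks in _PEAK_PLAN.items():
        w = np.full(N_CHANNELS, 1.0, dtype=float)
        if name == "SBS5":
            w += rng.gamma(8.0, 1.0, size=N_CHANNELS)  # broad, mildly rough
        for block, slots in peaks:
            for s in slots:
                w[block * 16 + s] += 60.0 + rng.uniform(0, 20)
        names.append(name)
        cols.append(w / w.sum())
    for i in range(n_nuisance):
        w = rng.gamma(0.25, 1.0, size=N_CHANNELS) + 1e-4
        names.append(f"NS{i + 1}")
        cols.append(w / w.sum())
    return SignatureCatalog(names, np.stack(cols, axis=1))


# ---------------------------------------------------------------------------
# Toy gene model
# ---------------------------------------------------------------------------

_NAMED_GENES = {
    "TP53": 1182, "NF1": 8520, "SETD2": 7695, "ATRX": 7479, "PRKDC": 12387,
    "EPHB2": 3165, "DICER1": 5769, "POLE": 6861, "POLD1": 3324,
    "TP53BP1": 5919, "PPM1D": 1818, "KMT2B": 8163, "DMD": 11058,
    "MYO10": 6165, "MYO9B": 6423, "MYH6": 5820, "HYDIN": 14000,
    "DNAH11": 13578, "IDH1": 1245, "EGFR": 3633,
}


@dataclass
class ToyGeneModel:
    """Stand-in for an exome gene annotation: coding lengths and the
    probability that a random coding SNV is synonymous."""

    lengths: dict[str, int]
    syn_fraction: float = DEFAULT_SYN_FRACTION

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("gene lengths must be positive")
        if not 0.0 < self.syn_fraction < 1.0:
            raise ValueError("syn_fraction must lie in (0,1)")

    @property
    def genes(self) -> list[str]:
        return list(self.lengths)


def default_gene_model(n_filler: int = 40) -> ToyGeneModel:
    """60-gene toy exome: 20 named cancer/recurrence genes + filler."""
    lengths = dict(_NAMED_GENES)
    for i in range(n_filler):
        lengths[f"G{i + 1:03d}"] = 1000 + (i * 337) % 14000
    return ToyGeneModel(lengths=lengths)


# ---------------------------------------------------------------------------
# Truth specification
# ---------------------------------------------------------------------------

@dataclass
class BurstSpec:
    vaf_center: float
    n_mutations: int
    exposure: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf_center < 1.0:
            raise ValueError("vaf_center must lie in (0,1)")
        if self.n_mutations <= 0:
            raise ValueError("n_mutations must be positive")
        tot = sum(self.exposure.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"exposure sums to {tot}, not 1")


@dataclass
class DriverSpec:
    gene: str  # "POLE" | "POLD1"
    vaf_true: float
    burst_index: int
    protein_change: str = "P286R"


@dataclass
class PatientTruth:
    patient_id: str
    bursts: list[BurstSpec]
    driver: DriverSpec | None = None
    planted_genes: dict[str, list[tuple[float, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.driver is not None:
            top = max(range(len(self.bursts)),
                      key=lambda i: self.bursts[i].vaf_center)
            if self.driver.burst_index != top:
                raise ValueError(
                    "driver must sit in the burst with the highest VAF center")


@dataclass
class TruthSet:
    patients: list[PatientTruth]
    depth_mean: float = DEFAULT_DEPTH_MEAN
    exome_mb: float = DEFAULT_EXOME_MB
    seed: int = 0

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "depth_mean": self.depth_mean,
            "exome_mb": self.exome_mb,
            "patients": [
                {
                    "patient_id": p.patient_id,
                    "bursts": [
                        {"vaf_center": b.vaf_center, "n_mutations": b.n_mutations,
                         "exposure": b.exposure} for b in p.bursts
                    ],
                    "driver": None if p.driver is None else {
                        "gene": p.driver.gene, "vaf_true": p.driver.vaf_true,
                        "burst_index": p.driver.burst_index,
                        "protein_change": p.driver.protein_change,
                    },
                    "planted_genes": {
                        g: [[v, e] for v, e in hits]
                        for g, hits in p.planted_genes.items()
                    },
                }
                for p in self.patients
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        doc = json.loads(Path(path).read_text())
        patients = []
        for p in doc["patients"]:
            driver = None
            if p["driver"] is not None:
                driver = DriverSpec(**p["driver"])
            patients.append(PatientTruth(
                patient_id=p["patient_id"],
                bursts=[BurstSpec(**b) for b in p["bursts"]],
                driver=driver,
                planted_genes={g: [(float(v), str(e)) for v, e in hits]
                               for g, hits in p["planted_genes"].items()},
            ))
        return cls(patients=patients, depth_mean=doc["depth_mean"],
                   exome_mb=doc["exome_mb"], seed=doc["seed"])


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_depths(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    """Poisson depths truncated below at DEPTH_FLOOR (resampled)."""
    d = rng.poisson(mean, size=n)
    while (low := d < DEPTH_FLOOR).any():
        d[low] = rng.poisson(mean, size=int(low.sum()))
    return d


def _mixture_vector(exposure: dict[str, float], catalog: SignatureCatalog) -> np.ndarray:
    p = np.zeros(N_CHANNELS)
    for name, w in exposure.items():
        if name not in catalog.signature_names:
            raise ValueError(f"exposure references unknown signature {name!r}")
        p += w * catalog.column(name)
    return p / p.sum()


def simulate_patient(truth: PatientTruth, catalog: SignatureCatalog,
                     genes: ToyGeneModel, seed: int,
                     depth_mean: float = DEFAULT_DEPTH_MEAN,
                     strand_flip: bool = False) -> list[MutationRecord]:
    """Generate one patient's somatic SNV catalog from its truth entry.

    Burst records are appended in burst order; the planted recurrent
    gene hits and finally the driver mutation follow. ``strand_flip``
    randomly reverse-complements half the records (their channel is
    unchanged after pyrimidine normalization, which tests exactly that).
    """
    rng = np.random.default_rng(seed)
    gene_names = genes.genes
    gene_p = np.array([genes.lengths[g] for g in gene_names], dtype=float)
    gene_p /= gene_p.sum()
    records: list[MutationRecord] = []
    pos = 0

    def emit(channel: int, gene: str, effect: str, depth: int, alt_reads: int,
             protein_change: str | None = None) -> None:
        nonlocal pos
        pos += 1
        ref, alt, ctx = decode_channel(channel)
        if strand_flip and rng.random() < 0.5:
            ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
        records.append(MutationRecord(
            patient_id=truth.patient_id, chrom="chrS", pos=pos,
            ref=ref, alt=alt, gene=gene, effect=effect, context3=ctx,
            alt_reads=alt_reads, depth=depth, vaf=alt_reads / depth,
            protein_change=protein_change,
        ))

    first_mix = None
    for burst in truth.bursts:
        n = burst.n_mutations
        mix = _mixture_vector(burst.exposure, catalog)
        if first_mix is None:
            first_mix = mix
        channels = rng.choice(N_CHANNELS, size=n, p=mix)
        burst_genes = rng.choice(len(gene_names), size=n, p=gene_p)
        synon = rng.random(n) < genes.syn_fraction
        depths = _sample_depths(rng, n, depth_mean)
        alts = rng.binomial(depths, burst.vaf_center)
        for ch, gi, syn, d, a in zip(channels, burst_genes, synon, depths, alts):
            emit(int(ch), gene_names[int(gi)],
                 "synonymous" if syn else "missense", int(d), int(a))

    def emit_single(gene: str, effect: str, vaf_true: float,
                    protein_change: str | None = None) -> None:
        ch = int(rng.choice(N_CHANNELS, p=first_mix))
        d = int(_sample_depths(rng, 1, depth_mean)[0])
        emit(ch, gene, effect, d, int(rng.binomial(d, vaf_true)),
             protein_change=protein_change)

    for gene, hits in sorted(truth.planted_genes.items()):
        for vaf_true, effect in hits:
            emit_single(gene, effect, vaf_true)

    if truth.driver is not None:
        emit_single(truth.driver.gene, "missense", truth.driver.vaf_true,
                    protein_change=truth.driver.protein_change)
    return records


# ---------------------------------------------------------------------------
# Cohort configuration and simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort."""

    truth: TruthSet
    catalog: SignatureCatalog = field(default_factory=synthetic_catalog)
    genes: ToyGeneModel = field(default_factory=default_gene_model)
    mmr_gene_by_patient: dict[str, str] = field(default_factory=dict)


# per-patient conditions of the default cohort: TMB (coding SNV/Mb),
# driver gene (or None), driver true VAF, number of bursts, and whether
# later bursts dominate the first one
_DEFAULT_PATIENT_PLAN = [
    # pid, tmb, driver, driver_vaf, n_bursts, late_heavy, mmr_gene
    ("P01", 1.3, None, None, 1, False, "PMS2"),
    ("P02", 63.0, "POLD1", 0.453, 2, True, "PMS2"),
    ("P03", 88.0, None, None, 1, False, "PMS2"),
    ("P04", 104.0, None, None, 2, False, "PMS2"),
    ("P05", 152.0, "POLE", 0.40, 2, False, "PMS2"),
    ("P06", 170.0, "POLE", 0.38, 3, False, "PMS2"),
    ("P07", 179.0, "POLE", 0.42, 2, False, "PMS2"),
    ("P08", 204.0, "POLE", 0.40, 3, False, "MSH6"),
    ("P09", 220.0, "POLE", 0.35, 3, True, "MSH6"),
    ("P10", 279.0, "POLE", 0.40, 3, False, "MSH6"),
    ("P11", 380.0, "POLE", 0.44, 4, False, "MSH6"),
    ("P12", 635.0, "POLE", 0.40, 4, True, "MSH6"),
]

# later bursts sit at fixed offsets below the clonal (driver) burst
_BURST_OFFSETS = [0.0, 0.14, 0.26, 0.37]

_EXPOSURE_POLE = {"SBS15": 0.50, "SBS14": 0.12, "SBS10a": 0.08, "SBS10b": 0.05,
                  "SBS5": 0.15, "SBS1": 0.10}
_EXPOSURE_POLD1 = {"SBS20": 0.55, "SBS15": 0.25, "SBS5": 0.20}
_EXPOSURE_NONE = {"SBS15": 0.65, "SBS5": 0.25, "SBS1": 0.10}

# recurrent above-driver genes: gene -> patients with 2 hits (others get 1)
_PLANT_PLAN = {
    "TP53": (8, 4), "NF1": (9, 3), "SETD2": (9, 2), "PRKDC": (8, 5),
    "EPHB2": (8, 0), "DICER1": (8, 0), "ATRX": (8, 3),
}


def default_cohort_truth(exome_mb: float = DEFAULT_EXOME_MB,
                         depth_mean: float = DEFAULT_DEPTH_MEAN,
                         scale: float = 1.0, seed: int = 0) -> TruthSet:
    """The default 12-patient cohort: 9 polymerase drivers (8 POLE, 1
    POLD1), TMB spanning ~1-635 coding SNV/Mb, 1-4 bursts per tumor.

    ``scale`` shrinks every burst proportionally (minimum 30 mutations
    per burst) for quick smoke runs; 1.0 is the full-size cohort.
    """
    rng = np.random.default_rng(seed)
    patients = []
    n_pat = len(_DEFAULT_PATIENT_PLAN)
    for pi, (pid, tmb, drv, dvaf, n_bursts, late_heavy, _mmr) in enumerate(
            _DEFAULT_PATIENT_PLAN):
        total = max(int(round(tmb * exome_mb * scale)), n_bursts * 30)
        if n_bursts == 1:
            shares = [1.0]
        elif late_heavy:
            shares = [0.25] + [0.75 / (n_bursts - 1)] * (n_bursts - 1)
        else:
            shares = [0.55] + [0.45 / (n_bursts - 1)] * (n_bursts - 1)
        exposure = (_EXPOSURE_POLD1 if drv == "POLD1"
                    else _EXPOSURE_POLE if drv == "POLE" else _EXPOSURE_NONE)
        top = round(dvaf, 3) if drv is not None else 0.40
        centers = [max(round(top - off, 3), 0.05)
                   for off in _BURST_OFFSETS[:n_bursts]]
        bursts = [
            BurstSpec(vaf_center=c, n_mutations=max(int(round(total * s)), 30),
                      exposure=dict(exposure))
            for c, s in zip(centers, shares)
        ]
        driver = None
        if drv is not None:
            driver = DriverSpec(gene=drv, vaf_true=dvaf, burst_index=0,
                                protein_change="P286R" if drv == "POLE" else "D402N")
        planted: dict[str, list[tuple[float, str]]] = {}
        for gene, (n_carriers, n_double) in _PLANT_PLAN.items():
            if pi < n_carriers:  # deterministic carrier choice
                n_hits = 2 if pi < n_double else 1
                planted[gene] = [
                    (float(np.round(0.47 + 0.05 * rng.random(), 3)),
                     "missense" if rng.random() < 0.7 else "nonsense")
                    for _ in range(n_hits)
                ]
        patients.append(PatientTruth(patient_id=pid, bursts=bursts,
                                     driver=driver, planted_genes=planted))
    return TruthSet(patients=patients, depth_mean=depth_mean,
                    exome_mb=exome_mb, seed=seed)


def default_cohort_config(scale: float = 1.0, seed: int = 0,
                          exome_mb: float = DEFAULT_EXOME_MB) -> CohortConfig:
    truth = default_cohort_truth(exome_mb=exome_mb, scale=scale, seed=seed)
    mmr = {pid: mmr_gene for pid, *_rest, mmr_gene in _DEFAULT_PATIENT_PLAN}
    return CohortConfig(truth=truth, mmr_gene_by_patient=mmr)


@dataclass
class CohortSim:
    tables: dict[str, list[MutationRecord]]
    truth: TruthSet
    clinical: list[ClinicalAnnotation]


def simulate_cohort(config: CohortConfig, seed: int,
                    out_dir: str | Path | None = None) -> CohortSim:
    """Simulate every patient; optionally write tables + truth + clinical."""
    rng = np.random.default_rng(seed)
    tables: dict[str, list[MutationRecord]] = {}
    for i, pt in enumerate(config.truth.patients):
        tables[pt.patient_id] = simulate_patient(
            pt, config.catalog, config.genes,
            seed=int(rng.integers(0, 2**31 - 1)),
            depth_mean=config.truth.depth_mean,
        )
    clinical = _synthetic_clinical(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid, recs in tables.items():
            write_mutation_table(recs, out / f"{pid}.muts.tsv")
        config.truth.to_json(out / "truth.json")
        _write_clinical(clinical, out / "clinical.tsv")
    return CohortSim(tables=tables, truth=config.truth, clinical=clinical)


def _synthetic_clinical(config: CohortConfig) -> list[ClinicalAnnotation]:
    """Deterministic clinical annotations for simulated patients (stain
    patterns shaped like a small MMR-deficient glioma cohort)."""
    out = []
    for i, pt in enumerate(config.truth.patients):
        mmr = config.mmr_gene_by_patient.get(pt.patient_id,
                                             "PMS2" if i % 2 == 0 else "MSH6")
        out.append(ClinicalAnnotation(
            patient_id=pt.patient_id, mmr_gene=mmr,
            histology_text=("GBM (with few giant multi-nucleated cells)"
                            if i % 3 != 2 else "GBM"),
            atrx_loss=1 if i % 4 != 3 else 0,
            p53_staining=1,
            pdl1_score=(i % 3),
            cd8_infiltrate=1 if i % 2 == 0 else 0,
        ))
    return out


def _write_clinical(annotations: list[ClinicalAnnotation], path) -> None:
    import pandas as pd

    rows = [{
        "patient_id": a.patient_id, "mmr_gene": a.mmr_gene,
        "histology": a.histology_text,
        "atrx_loss": "NA" if a.atrx_loss is None else a.atrx_loss,
        "p53_staining": "NA" if a.p53_staining is None else a.p53_staining,
        "pdl1_score": "NA" if a.pdl1_score is None else a.pdl1_score,
        "cd8_infiltrate": "NA" if a.cd8_infiltrate is None else a.cd8_infiltrate,
    } for a in annotations]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
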