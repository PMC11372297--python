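"""SBS96 spectra: channel counting and substitution-class summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, N_CHANNELS, SUBSTITUTION_CLASSES, classify_channel
from .io_formats import MutationRecord


@dataclass
class SpectrumVector:
    """Counts over the 96 canonical trinucleotide channels."""

    counts: np.ndarray  # (96,) non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CHANNELS,):
            raise ValueError(f"expected 96 channels, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.n_total == 0:
            raise ValueError("empty spectrum has no frequencies")
        return self.counts / self.n_total

    def __add__(self, other: "SpectrumVector") -> "SpectrumVector":
        return SpectrumVector(self.counts + other.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"Type": list(CHANNEL_LABELS), "count": self.counts})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectrumVector":
        df = pd.read_csv(path, sep="\t")
        order = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}
        counts = np.zeros(N_CHANNELS, dtype=np.int64)
        for lab, c in zip(df.iloc[:, 0], df.iloc[:, 1]):
            counts[order[str(lab)]] += int(c)
        return cls(counts)


def build_spectrum(records: Iterable[MutationRecord]) -> SpectrumVector:
    """Count records into the 96 channels (order-independent, additive)."""
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    for r in records:
        counts[classify_channel(r.ref, r.alt, r.context3)] += 1
    return SpectrumVector(counts)


# alias names used in cancer-genomics reports for the two dominant classes
CLASS_ALIASES: Mapping[str, str] = {
    "G:C>A:T transitions": "C>T",
    "C:G>A:T transversions": "C>A",
}


def class_fractions(spectrum: SpectrumVector) -> dict[str, float]:
    """Fractions of the six pyrimidine substitution classes.

    Also reports the purine/pyrimidine-pair aliases commonly quoted for
    MMR-deficient tumors: G:C>A:T transitions (the C>T class) and
    C:G>A:T transversions (the C>A class).
    """
    if spectrum.n_total == 0:
        raise ValueError("cannot compute class fractions of an empty spectrum")
    per_class = spectrum.counts.reshape(6, 16).sum(axis=1)
    fracs = {cls: float(v) / spectrum.n_total
             for cls, v in zip(SUBSTITUTION_CLASSES, per_class)}
    for alias, cls in CLASS_ALIASES.items():
        fracs[alias] = fracs[cls]
    return fracs
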