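"""Supervised signature refitting.

Given an observed SBS96 spectrum and a fixed signature catalog, estimate
non-negative exposures (mutation counts attributed to each signature)
that reconstruct the spectrum. Signatures are chosen by greedy forward
selection: starting from the empty set, the signature whose inclusion
most increases the cosine similarity between the observed frequency
vector and its non-negative least-squares reconstruction is added,
until the best achievable gain drops below ``gain_threshold``. The
final exposures are the NNLS solution on the selected set, rescaled to
sum to the observed mutation count. The procedure is deterministic;
ties in forward selection go to the lowest catalog column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .io_formats import MutationRecord, SignatureCatalog
from .spectrum import SpectrumVector, build_spectrum

DEFAULT_GAIN_THRESHOLD = 0.02
DEFAULT_MIN_SUBSET_SIZE = 50


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass
class ExposureEstimate:
    """Result of a supervised refit.

    ``exposures`` maps each selected signature to its attributed
    mutation count (non-negative, summing to ``n_total``); ``cosine``
    is the similarity between the observed spectrum and its
    reconstruction from the selected signatures.
    """

    exposures: dict[str, float]
    cosine: float
    n_total: int
    selection_path: list[tuple[str, float]] = field(default_factory=list)
    too_small: bool = False

    @property
    def selected(self) -> list[str]:
        return [s for s, v in self.exposures.items() if v > 0]

    def fractions(self) -> dict[str, float]:
        tot = sum(self.exposures.values())
        if tot == 0:
            return {s: 0.0 for s in self.exposures}
        return {s: v / tot for s, v in self.exposures.items()}

    def frequency_vector(self, catalog: SignatureCatalog) -> np.ndarray:
        """Exposure fractions aligned to the catalog's column order."""
        fr = self.fractions()
        return np.array([fr.get(s, 0.0) for s in catalog.signature_names])

    def summary(self) -> str:
        lines = [
            "Supervised signature refit",
            f"  mutations: {self.n_total}",
            f"  reconstruction cosine: {self.cosine:.4f}",
            f"  {'signature':<12}{'exposure':>12}{'fraction':>10}",
        ]
        tot = max(sum(self.exposures.values()), 1.0)
        for s, v in sorted(self.exposures.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {s:<12}{v:>12.1f}{v / tot:>10.3f}")
        return "\n".join(lines)


class SignatureRefit:
    """Model object binding one observed spectrum to a signature catalog."""

    def __init__(self, spectrum: SpectrumVector, catalog: SignatureCatalog):
        if catalog.n_signatures == 0:
            raise ValueError("empty signature catalog")
        if spectrum.n_total == 0:
            raise ValueError("cannot refit an empty spectrum")
        self.spectrum = spectrum
        self.catalog = catalog
        self._target = spectrum.frequencies()

    def _nnls_cosine(self, columns: list[int]) -> tuple[np.ndarray, float]:
        A = self.catalog.weights[:, columns]
        coef, _ = nnls(A, self._target)
        recon = A @ coef
        return coef, cosine_similarity(recon, self._target)

    def fit(self, gain_threshold: float = DEFAULT_GAIN_THRESHOLD) -> ExposureEstimate:
        selected: list[int] = []
        best_cos = 0.0
        path: list[tuple[str, float]] = []
        remaining = list(range(self.catalog.n_signatures))
        while remaining:
            gains = np.full(len(remaining), -np.inf)
            for j, col in enumerate(remaining):
                _, cos = self._nnls_cosine(selected + [col])
                gains[j] = cos - best_cos
            j_best = int(np.argmax(gains))  # argmax takes first max: lowest index wins ties
            if gains[j_best] < gain_threshold:
                break
            if gain_threshold >= 0:
                # greedy cosine must be non-decreasing across accepted steps
                assert gains[j_best] >= 0, "cosine decreased in forward selection"
            col = remaining.pop(j_best)
            selected.append(col)
            best_cos += gains[j_best]
            path.append((self.catalog.signature_names[col], best_cos))

        if not selected:
            return ExposureEstimate(exposures={}, cosine=0.0,
                                    n_total=self.spectrum.n_total, selection_path=path)
        coef, cos = self._nnls_cosine(selected)
        total = coef.sum()
        scale = self.spectrum.n_total / total if total > 0 else 0.0
        exposures = {
            self.catalog.signature_names[c]: float(w * scale)
            for c, w in zip(selected, coef)
        }
        return ExposureEstimate(exposures=exposures, cosine=cos,
                                n_total=self.spectrum.n_total, selection_path=path)


def refit(spectrum: SpectrumVector, catalog: SignatureCatalog,
          gain_threshold: float = DEFAULT_GAIN_THRESHOLD) -> ExposureEstimate:
    """Functional wrapper around :class:`SignatureRefit`."""
    return SignatureRefit(spectrum, catalog).fit(gain_threshold=gain_threshold)


def refit_subsets(records: list[MutationRecord], subset_assignment: list[int],
                  catalog: SignatureCatalog,
                  gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
                  min_size: int = DEFAULT_MIN_SUBSET_SIZE) -> dict[int, ExposureEstimate]:
    """Independent refits per record subset (e.g. per mutation burst).

    Subsets smaller than ``min_size`` are reported with
    ``too_small=True`` instead of being fitted.
    """
    if len(records) != len(subset_assignment):
        raise ValueError("one subset id required per record")
    by_subset: dict[int, list[MutationRecord]] = {}
    for rec, sid in zip(records, subset_assignment):
        by_subset.setdefault(sid, []).append(rec)
    out: dict[int, ExposureEstimate] = {}
    for sid in sorted(by_subset):
        subset = by_subset[sid]
        if len(subset) < min_size:
            out[sid] = ExposureEstimate(exposures={}, cosine=0.0,
                                        n_total=len(subset), too_small=True)
        else:
            out[sid] = refit(build_spectrum(subset), catalog, gain_threshold)
    return out
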