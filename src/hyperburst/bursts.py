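"""Mutation-burst detection from the VAF distribution.

A tumor's somatic VAF histogram typically shows several modes
("mutation bursts"), each a temporally coherent wave of mutation
accumulation. Bursts are modelled here as components of a K-component
binomial mixture over the raw read counts: a mutation with depth d and
burst VAF p contributes alt reads ~ Binomial(d, p). Modelling counts
rather than the VAF ratio keeps the depth-dependent noise explicit.
K is chosen by BIC over 1..k_max; each K is fitted by EM from several
seeded quantile-spaced initialisations. A Gaussian-on-VAF fallback is
available for tables without read counts.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from scipy.special import gammaln

from .io_formats import MutationRecord

logger = logging.getLogger(__name__)

DEFAULT_K_MAX = 6
DEFAULT_RESTARTS = 10
MIN_RECORDS = 20
_P_FLOOR = 1e-6


@dataclass
class BurstComponent:
    vaf_center: float
    weight: float
    n_assigned: int


@dataclass
class BurstModel:
    """Fitted mixture over VAF: burst centers, weights and assignments.

    Components are ordered by decreasing ``vaf_center`` so index 0 is
    the earliest ("first") burst. ``assignment[i]`` is the hard
    maximum-posterior component of record i (ties to the lower index).
    """

    components: list[BurstComponent]
    assignment: np.ndarray
    loglik: float
    bic: float
    n_records: int
    family: str = "binomial"

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def centers(self) -> np.ndarray:
        return np.array([c.vaf_center for c in self.components])

    def summary(self) -> str:
        lines = [
            f"Burst mixture ({self.family}), K={self.K}, "
            f"n={self.n_records}, BIC={self.bic:.1f}",
            f"  {'burst':<7}{'VAF center':>11}{'weight':>9}{'n':>8}",
        ]
        for i, c in enumerate(self.components):
            lines.append(f"  {i:<7}{c.vaf_center:>11.3f}{c.weight:>9.3f}{c.n_assigned:>8}")
        return "\n".join(lines)


class _EMDegenerate(RuntimeError):
    pass


def _binom_em(x: np.ndarray, d: np.ndarray, w: np.ndarray, p0: np.ndarray,
              max_iter: int = 500, tol: float = 1e-9) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted EM on unique (alt, depth) pairs; returns (p, mix, loglik).

    The log-likelihood is asserted non-decreasing on every iteration.
    """
    n = w.sum()
    K = len(p0)
    p = np.clip(p0.astype(float), _P_FLOOR, 1 - _P_FLOOR)
    mix = np.full(K, 1.0 / K)
    log_choose = gammaln(d + 1) - gammaln(x + 1) - gammaln(d - x + 1)
    prev_ll = -np.inf
    for _ in range(max_iter):
        logp = (np.log(mix)[None, :]
                + x[:, None] * np.log(p)[None, :]
                + (d - x)[:, None] * np.log1p(-p)[None, :])
        m = logp.max(axis=1)
        norm = m + np.log(np.exp(logp - m[:, None]).sum(axis=1))
        ll = float(np.dot(w, norm + log_choose))
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), \
            "EM log-likelihood decreased"
        if ll - prev_ll < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
        r = np.exp(logp - norm[:, None]) * w[:, None]
        rk = r.sum(axis=0)
        mix = np.maximum(rk / n, 1e-12)
        mix /= mix.sum()
        p = np.clip((r * x[:, None]).sum(axis=0) / np.maximum((r * d[:, None]).sum(axis=0), 1e-12),
                    _P_FLOOR, 1 - _P_FLOOR)
    return p, mix, prev_ll


class BinomialMixture:
    """Model object for a K-component binomial mixture over read counts."""

    def __init__(self, alt_reads: np.ndarray, depth: np.ndarray):
        alt_reads = np.asarray(alt_reads, dtype=np.int64)
        depth = np.asarray(depth, dtype=np.int64)
        if alt_reads.shape != depth.shape or alt_reads.ndim != 1:
            raise ValueError("alt_reads and depth must be parallel 1-D arrays")
        if (depth <= 0).any() or (alt_reads < 0).any() or (alt_reads > depth).any():
            raise ValueError("require 0 <= alt_reads <= depth, depth > 0")
        self.alt_reads = alt_reads
        self.depth = depth
        self.n = len(alt_reads)
        # collapse to unique (alt, depth) pairs for fast weighted EM
        pairs = np.stack([alt_reads, depth], axis=1)
        uniq, self._inverse, counts = np.unique(
            pairs, axis=0, return_inverse=True, return_counts=True
        )
        self._ux = uniq[:, 0].astype(float)
        self._ud = uniq[:, 1].astype(float)
        self._uw = counts.astype(float)
        self.vaf = alt_reads / depth

    def _init_centers(self, k: int, rng: np.random.Generator, jitter: bool) -> np.ndarray:
        q = (np.arange(k) + 0.5) / k
        centers = np.quantile(self.vaf, q)
        if jitter:
            centers = centers + rng.normal(0.0, 0.02, size=k)
        return np.clip(centers, 0.01, 0.99)

    def fit(self, k: int, seed: int = 0,
            n_restarts: int = DEFAULT_RESTARTS) -> BurstModel:
        """Fit a K-component mixture; best of ``n_restarts`` seeded EM runs."""
        rng = np.random.default_rng(seed)
        best: tuple[float, np.ndarray, np.ndarray] | None = None
        for restart in range(n_restarts):
            p0 = self._init_centers(k, rng, jitter=restart > 0)
            p, mix, ll = _binom_em(self._ux, self._ud, self._uw, p0)
            if best is None or ll > best[0]:
                best = (ll, p, mix)
        ll, p, mix = best
        # posterior hard assignment on unique pairs, then expand
        logp = (np.log(mix)[None, :]
                + self._ux[:, None] * np.log(p)[None, :]
                + (self._ud - self._ux)[:, None] * np.log1p(-p)[None, :])
        order = np.argsort(-p, kind="stable")  # highest-VAF burst first
        logp = logp[:, order]
        p, mix = p[order], mix[order]
        assign_u = np.argmax(logp, axis=1)  # ties -> lower index
        assignment = assign_u[self._inverse]
        n_assigned = np.bincount(assignment, minlength=k)
        n_params = 2 * k - 1  # k centers + k-1 free mixing weights
        bic = -2.0 * ll + n_params * np.log(self.n)
        comps = [BurstComponent(float(p[j]), float(mix[j]), int(n_assigned[j]))
                 for j in range(k)]
        return BurstModel(components=comps, assignment=assignment,
                          loglik=ll, bic=bic, n_records=self.n)


class GaussianVAFMixture:
    """Gaussian-on-VAF fallback for tables lacking read counts."""

    def __init__(self, vaf: np.ndarray):
        self.vaf = np.asarray(vaf, dtype=float)
        self.n = len(self.vaf)

    def fit(self, k: int, seed: int = 0, n_restarts: int = DEFAULT_RESTARTS) -> BurstModel:
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=k, n_init=n_restarts,
                             random_state=int(seed) % (2**31), reg_covar=1e-5)
        gm.fit(self.vaf[:, None])
        order = np.argsort(-gm.means_.ravel(), kind="stable")
        means = gm.means_.ravel()[order]
        weights = gm.weights_[order]
        post = gm.predict_proba(self.vaf[:, None])[:, order]
        assignment = np.argmax(post, axis=1)
        n_assigned = np.bincount(assignment, minlength=k)
        ll = float(gm.score(self.vaf[:, None]) * self.n)
        n_params = 3 * k - 1
        comps = [BurstComponent(float(means[i]), float(weights[i]), int(n_assigned[i]))
                 for i in range(k)]
        return BurstModel(components=comps, assignment=assignment, loglik=ll,
                          bic=-2 * ll + n_params * np.log(self.n),
                          n_records=self.n, family="gaussian")


def fit_bursts(records: list[MutationRecord], k_max: int = DEFAULT_K_MAX,
               seed: int = 0, family: str = "binomial") -> BurstModel:
    """Detect mutation bursts: fit K=1..k_max mixtures, keep the lowest BIC."""
    if len(records) < MIN_RECORDS:
        raise ValueError(
            f"only {len(records)} records (< {MIN_RECORDS}); treat the tumor "
            "as a single burst instead of fitting a mixture"
        )
    if family == "binomial":
        model = BinomialMixture(
            np.array([r.alt_reads for r in records]),
            np.array([r.depth for r in records]),
        )
    elif family == "gaussian":
        model = GaussianVAFMixture(np.array([r.vaf for r in records]))
    else:
        raise ValueError(f"unknown family {family!r}")
    best: BurstModel | None = None
    for k in range(1, k_max + 1):
        fit = model.fit(k, seed=seed + k)
        if best is None or fit.bic < best.bic:
            best = fit
    return best


def qualify_bursts(model: BurstModel, min_mutations: int = 500,
                   min_fraction: float = 0.05) -> list[int]:
    """Indices of bursts large enough for per-burst signature analysis.

    A burst qualifies iff it holds strictly more than ``min_mutations``
    mutations AND strictly more than ``min_fraction`` of the total.
    """
    out = []
    for i, c in enumerate(model.components):
        if c.n_assigned > min_mutations and c.n_assigned / model.n_records > min_fraction:
            out.append(i)
    return out


def locate_driver_burst(model: BurstModel, records: list[MutationRecord],
                        driver_record: MutationRecord) -> tuple[int, bool]:
    """Component holding the driver mutation, and whether that component
    has the highest VAF center (the "first" burst)."""
    try:
        idx = next(i for i, r in enumerate(records) if r is driver_record
                   or (r.patient_id == driver_record.patient_id
                       and r.chrom == driver_record.chrom
                       and r.pos == driver_record.pos
                       and r.alt == driver_record.alt))
    except StopIteration:
        raise ValueError("driver record not among the fitted records") from None
    comp = int(model.assignment[idx])
    highest = comp == int(np.argmax(model.centers))
    if not highest:
        logger.warning(
            "driver mutation assigned to burst %d (center %.3f), not the "
            "highest-VAF burst", comp, model.components[comp].vaf_center,
        )
    return comp, highest
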