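"""Synthetic cohort generator: determinism, planted structure, noise model."""

import filecmp

import numpy as np
import pytest
from scipy.stats import ks_2samp

from hyperburst import (
    BurstSpec,
    PatientTruth,
    DriverSpec,
    TruthSet,
    default_cohort_config,
    default_gene_model,
    simulate_cohort,
    simulate_patient,
)
from hyperburst.channels import N_CHANNELS, classify_channel
from hyperburst.io_formats import SignatureCatalog
from hyperburst.simulate import default_cohort_truth
from hyperburst.spectrum import build_spectrum


def _delta_catalog(channel_idx: int) -> SignatureCatalog:
    w = np.zeros((N_CHANNELS, 1))
    w[channel_idx, 0] = 1.0
    return SignatureCatalog(["DELTA"], w)


def test_delta_catalog_degenerate_burst():
    """Exposure 100% on a delta column concentrated on A[C>T]G: every
    record is C>T in ACG context."""
    idx = classify_channel("C", "T", "ACG")
    truth = PatientTruth("T", [BurstSpec(0.4, 200, {"DELTA": 1.0})])
    recs = simulate_patient(truth, _delta_catalog(idx), default_gene_model(), seed=1)
    assert len(recs) == 200
    assert all((r.ref, r.alt, r.context3) == ("C", "T", "ACG") for r in recs)


def test_observed_vaf_mean_matches_monte_carlo_oracle(catalog):
    truth = PatientTruth("T", [BurstSpec(0.4, 5000, {"SBS15": 1.0})])
    recs = simulate_patient(truth, catalog, default_gene_model(), seed=1,
                            depth_mean=150)
    mean_vaf = float(np.mean([r.vaf for r in recs]))
    assert mean_vaf == pytest.approx(0.4, abs=0.01)
    # direct Monte-Carlo oracle of the same depth/binomial model
    rng = np.random.default_rng(999)
    d = np.maximum(rng.poisson(150, 5000), 20)
    oracle = float(np.mean(rng.binomial(d, 0.4) / d))
    assert mean_vaf == pytest.approx(oracle, abs=0.01)


def test_observed_vaf_distribution_ks(catalog):
    """Per-burst observed VAFs follow Binomial(depth, vaf_true)/depth:
    two-sample KS against an independent oracle sample stays below the
    1% critical value at n=5000."""
    truth = PatientTruth("T", [BurstSpec(0.35, 5000, {"SBS15": 1.0})])
    recs = simulate_patient(truth, catalog, default_gene_model(), seed=5)
    obs = np.array([r.vaf for r in recs])
    rng = np.random.default_rng(4242)
    d = rng.poisson(150, 5000)
    while (low := d < 20).any():
        d[low] = rng.poisson(150, int(low.sum()))
    ref = rng.binomial(d, 0.35) / d
    stat = ks_2samp(obs, ref).statistic
    crit = 1.628 * np.sqrt((len(obs) + len(ref)) / (len(obs) * len(ref)))
    assert stat < crit


def test_driver_planted_exactly_once(catalog):
    truth = PatientTruth(
        "T", [BurstSpec(0.40, 300, {"SBS15": 1.0}), BurstSpec(0.2, 300, {"SBS15": 1.0})],
        driver=DriverSpec(gene="POLE", vaf_true=0.40, burst_index=0),
    )
    recs = simulate_patient(truth, catalog, default_gene_model(), seed=2)
    drivers = [r for r in recs if r.protein_change is not None]
    assert len(drivers) == 1
    assert drivers[0].gene == "POLE"
    assert drivers[0].effect == "missense"


def test_driver_must_sit_in_highest_vaf_burst():
    with pytest.raises(ValueError, match="highest"):
        PatientTruth("T", [BurstSpec(0.40, 100, {"S": 1.0}),
                           BurstSpec(0.20, 100, {"S": 1.0})],
                     driver=DriverSpec(gene="POLE", vaf_true=0.2, burst_index=1))


def test_unknown_signature_in_exposure_errors(catalog):
    truth = PatientTruth("T", [BurstSpec(0.4, 50, {"NOPE": 1.0})])
    with pytest.raises(ValueError, match="NOPE"):
        simulate_patient(truth, catalog, default_gene_model(), seed=0)


def test_burst_counts_exact_in_output(catalog):
    truth = PatientTruth("T", [BurstSpec(0.4, 123, {"SBS15": 1.0}),
                               BurstSpec(0.15, 456, {"SBS5": 1.0})])
    recs = simulate_patient(truth, catalog, default_gene_model(), seed=3)
    assert len(recs) == 123 + 456  # no driver, no planted genes


def test_channel_frequency_recovery(catalog):
    """A 50,000-mutation single-signature burst reproduces the catalog
    column with cosine >= 0.99."""
    truth = PatientTruth("T", [BurstSpec(0.4, 50_000, {"SBS15": 1.0})])
    recs = simulate_patient(truth, catalog, default_gene_model(), seed=6)
    freq = build_spectrum(recs).frequencies()
    col = catalog.column("SBS15")
    cos = float(np.dot(freq, col) / (np.linalg.norm(freq) * np.linalg.norm(col)))
    assert cos >= 0.99


def test_strand_flip_leaves_spectrum_unchanged(catalog):
    truth = PatientTruth("T", [BurstSpec(0.4, 2000, {"SBS15": 1.0})])
    plain = simulate_patient(truth, catalog, default_gene_model(), seed=9)
    flipped = simulate_patient(truth, catalog, default_gene_model(), seed=9,
                               strand_flip=True)
    # flipping emits purine-strand encodings; spectra are identical
    assert any(r.ref in "AG" for r in flipped)
    assert np.array_equal(build_spectrum(plain).counts,
                          build_spectrum(flipped).counts)


def test_cohort_determinism_and_shape(tmp_path):
    cfg = default_cohort_config(scale=0.01, seed=3)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    sim1 = simulate_cohort(cfg, seed=3, out_dir=d1)
    sim2 = simulate_cohort(default_cohort_config(scale=0.01, seed=3), seed=3,
                           out_dir=d2)
    assert len(sim1.tables) == 12
    for f in sorted(d1.iterdir()):
        assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name

    truth = sim1.truth
    n_drivers = sum(1 for p in truth.patients if p.driver is not None)
    assert n_drivers == 9
    genes = {p.driver.gene for p in truth.patients if p.driver}
    assert genes == {"POLE", "POLD1"}

    # truth JSON round-trip
    back = TruthSet.from_json(d1 / "truth.json")
    assert len(back.patients) == len(truth.patients)
    for a, b in zip(back.patients, truth.patients):
        assert a.patient_id == b.patient_id
        assert [x.n_mutations for x in a.bursts] == [x.n_mutations for x in b.bursts]
        assert (a.driver is None) == (b.driver is None)


def test_default_truth_paper_like_shape():
    truth = default_cohort_truth()
    tmbs = sorted(sum(b.n_mutations for b in p.bursts) / truth.exome_mb
                  for p in truth.patients)
    assert len(truth.patients) == 12
    assert tmbs[0] < 5 and tmbs[-1] > 600          # spans ~1-635/Mb
    assert sum(1 for t in tmbs if t >= 100) == 9   # 9 ultra-hypermutated
    for p in truth.patients:
        if p.driver:
            assert 0.31 <= p.driver.vaf_true <= 0.46
            top = max(range(len(p.bursts)), key=lambda i: p.bursts[i].vaf_center)
            assert p.driver.burst_index == top
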