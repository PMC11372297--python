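import numpy as np
import pytest

from hyperburst import MutationRecord, SignatureCatalog, synthetic_catalog
from hyperburst.channels import N_CHANNELS, decode_channel


def make_record(ref="C", alt="T", context3="ACG", vaf=None, alt_reads=60,
                depth=150, gene="G001", effect="missense", patient_id="P",
                chrom="chr1", pos=1, protein_change=None) -> MutationRecord:
    if vaf is None:
        vaf = alt_reads / depth
    return MutationRecord(patient_id=patient_id, chrom=chrom, pos=pos, ref=ref,
                          alt=alt, gene=gene, effect=effect, context3=context3,
                          alt_reads=alt_reads, depth=depth, vaf=vaf,
                          protein_change=protein_change)


def records_at_vaf(n, vaf_true, depth_mean=150, seed=0, gene="G001",
                   effect="missense", patient_id="P", start_pos=1):
    """n records with binomial read noise around a true VAF."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        d = max(int(rng.poisson(depth_mean)), 20)
        a = int(rng.binomial(d, vaf_true))
        ref, alt, ctx = decode_channel(int(rng.integers(0, N_CHANNELS)))
        out.append(MutationRecord(patient_id=patient_id, chrom="chr1",
                                  pos=start_pos + i, ref=ref, alt=alt,
                                  gene=gene, effect=effect, context3=ctx,
                                  alt_reads=a, depth=d, vaf=a / d))
    return out


@pytest.fixture(scope="session")
def catalog() -> SignatureCatalog:
    return synthetic_catalog()


@pytest.fixture(scope="session")
def disjoint_catalog() -> SignatureCatalog:
    """Two toy signatures with disjoint channel support (10 channels each)."""
    a = np.zeros(N_CHANNELS)
    b = np.zeros(N_CHANNELS)
    a[:10] = 0.1
    b[20:30] = 0.1
    return SignatureCatalog(["SBSa", "SBSb"], np.stack([a, b], axis=1))
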