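import numpy as np
import pandas as pd
import pytest

from circsponge.model import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    MiRNA,
    Transcript,
)
from circsponge.simulate import CohortConfig, simulate_cohort

#: miRNA used throughout the seed-site tests; seed (nt 2-8) = AACGGUU, so
#: 7mer-m8 = AACCGTT, 8mer = AACCGTTA, 7mer-A1 = ACCGTTA.
SEED_MIRNA = MiRNA("miR-test", "UAACGGUUCACGGAA")


@pytest.fixture(scope="session")
def mirna():
    return SEED_MIRNA


def make_annotation(transcripts) -> GenomeAnnotation:
    """Build an annotation from (tid, gid, chrom, strand, exons[, utr3]) tuples."""
    ann = GenomeAnnotation()
    for spec in transcripts:
        tid, gid, chrom, strand, exons = spec[:5]
        utr3 = spec[5] if len(spec) > 5 else None
        ann.transcripts[tid] = Transcript(tid, gid, chrom, strand, list(exons), utr3)
        if gid not in ann.genes:
            ann.genes[gid] = Gene(gid, chrom, strand, exons[0][0], exons[-1][1])
    ann.validate()
    return ann


@pytest.fixture
def five_exon_annotation():
    """One '+' strand gene with five exons (a circRNA spanning exons 2-4)."""
    exons = [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]
    return make_annotation([("tx1", "HOSTG", "chr3", "+", exons)]), exons


def make_matrix(counts, subjects=None, conditions=None, features=None, samples=None):
    counts = np.asarray(counts)
    n_feat, n_samp = counts.shape
    features = features or [f"f{i}" for i in range(n_feat)]
    samples = samples or [f"s{i}" for i in range(n_samp)]
    meta = None
    if conditions is not None:
        meta = pd.DataFrame(
            {"subject_id": subjects or [f"subj{i}" for i in range(n_samp)],
             "condition": conditions},
            index=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(pd.DataFrame(counts, index=features, columns=samples), meta)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study (39 paired subjects), shared across tests."""
    return simulate_cohort(CohortConfig(), seed=20260)


@pytest.fixture(scope="session")
def small_config():
    """A fast, reduced cohort for tests that re-simulate repeatedly."""
    return CohortConfig(
        n_circ=40, n_mrna=70, n_mirna=5, n_planted_triplets=3,
        n_planted_dec_extra=2, n_decoy_pos=8, n_decoy_neg=8,
        n_kd_pos=3, n_kd_neg=2)
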