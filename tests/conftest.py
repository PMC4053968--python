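import numpy as np
import pytest

from lncsel import cohort
from lncsel.genomic import AnnotationSet, FeatureInterval


def small_cohort_config(**overrides):
    kw = dict(n_chromosomes=1, chrom_length=60_000, n_genes=4, n_lnc=4,
              n_ar=4, sample_n=20)
    kw.update(overrides)
    return cohort.CohortConfig(**kw)


@pytest.fixture(scope="session")
def tiny_cohort():
    """One small deterministic cohort shared across read-only tests."""
    bundle, truth = cohort.generate_cohort(small_cohort_config(), seed=11)
    return bundle, truth


@pytest.fixture
def toy_annotation():
    """Hand-built two-gene layout on a 10 kb chromosome.

    geneA (+): utr5 100-150, cds 150-250 / intron 250-330 / cds 330-430,
    utr3 430-530. lncB (-): three exons 2000-2150, 2350-2500, 2700-2850
    with the two introns filling the gaps. AR at 4000-4300.
    """
    feats = [
        FeatureInterval("chr1", 100, 150, "+", "utr5", "geneA", "unique"),
        FeatureInterval("chr1", 150, 250, "+", "cds_exon", "geneA",
                        "first"),
        FeatureInterval("chr1", 250, 330, "+", "pc_intron", "geneA",
                        "unique"),
        FeatureInterval("chr1", 330, 430, "+", "cds_exon", "geneA",
                        "last"),
        FeatureInterval("chr1", 430, 530, "+", "utr3", "geneA", "unique"),
        # minus strand: leftmost genomic exon is the transcript's last
        FeatureInterval("chr1", 2000, 2150, "-", "lnc_exon", "lncB",
                        "last"),
        FeatureInterval("chr1", 2150, 2350, "-", "lnc_intron", "lncB",
                        "last"),
        FeatureInterval("chr1", 2350, 2500, "-", "lnc_exon", "lncB",
                        "middle"),
        FeatureInterval("chr1", 2500, 2700, "-", "lnc_intron", "lncB",
                        "first"),
        FeatureInterval("chr1", 2700, 2850, "-", "lnc_exon", "lncB",
                        "first"),
        FeatureInterval("chr1", 4000, 4300, "+", "ancestral_repeat",
                        "arC", "unique"),
    ]
    ann = AnnotationSet(feats)
    ann.build_index({"chr1": 10_000})
    return ann


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
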