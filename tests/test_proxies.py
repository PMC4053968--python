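"""Neutral-proxy construction: small introns, flanking ancestral repeats,
conservation masking, matched flank sampling."""

import numpy as np
import pytest

from lncsel.genomic import AnnotationSet, FeatureInterval
from lncsel.proxies import (ProxySpec, mask_conserved_by_score,
                            mask_conserved_elements, matched_neutral_samples,
                            sample_matched_sites,
                            select_flanking_ancestral_repeats,
                            select_small_introns)


def annotation_with_intron(intron_len, gap=2_000, strand="+"):
    """One gene (two CDS exons around one intron) `gap` bp from one
    lncRNA."""
    g0 = 1_000
    feats = [
        FeatureInterval("chr1", g0, g0 + 90, strand, "cds_exon", "geneA",
                        "first" if strand == "+" else "last"),
        FeatureInterval("chr1", g0 + 90, g0 + 90 + intron_len, strand,
                        "pc_intron", "geneA", "unique"),
        FeatureInterval("chr1", g0 + 90 + intron_len,
                        g0 + 180 + intron_len, strand, "cds_exon", "geneA",
                        "last" if strand == "+" else "first"),
    ]
    l0 = g0 + 180 + intron_len + gap
    feats += [
        FeatureInterval("chr1", l0, l0 + 300, "+", "lnc_exon", "lncB",
                        "first"),
        FeatureInterval("chr1", l0 + 300, l0 + 500, "+", "lnc_intron",
                        "lncB", "unique"),
        FeatureInterval("chr1", l0 + 500, l0 + 800, "+", "lnc_exon",
                        "lncB", "last"),
    ]
    return AnnotationSet(feats)


class TestSmallIntrons:
    def test_trim_of_86nt_intron_leaves_64(self):
        ann = annotation_with_intron(86)
        out = select_small_introns(ann)
        assert len(out) == 1
        assert len(out[0]) == 86 - 6 - 16

    def test_87nt_intron_excluded(self):
        ann = annotation_with_intron(87)
        assert select_small_introns(ann) == []

    def test_gene_beyond_distance_threshold_excluded(self):
        ann = annotation_with_intron(80, gap=6_000)
        assert select_small_introns(ann, ProxySpec(max_distance=5_000)) \
            == []

    def test_trim_is_transcript_oriented(self):
        plus = select_small_introns(annotation_with_intron(86, strand="+"))
        minus = select_small_introns(annotation_with_intron(86,
                                                            strand="-"))
        raw_start = 1_000 + 90
        assert plus[0].start == raw_start + 6
        assert plus[0].end == raw_start + 86 - 16
        assert minus[0].start == raw_start + 16
        assert minus[0].end == raw_start + 86 - 6

    def test_trimmed_interval_never_covers_trim_zones(self):
        for strand in "+-":
            ann = annotation_with_intron(70, strand=strand)
            raw = next(f for f in ann.features
                       if f.feature_class == "pc_intron")
            out = select_small_introns(ann)[0]
            tx_first6 = (range(raw.start, raw.start + 6) if strand == "+"
                         else range(raw.end - 6, raw.end))
            tx_last16 = (range(raw.end - 16, raw.end) if strand == "+"
                         else range(raw.start, raw.start + 16))
            covered = set(range(out.start, out.end))
            assert covered.isdisjoint(tx_first6)
            assert covered.isdisjoint(tx_last16)


class TestFlankingARs:
    def make(self, ar_offset, inside_intron=False):
        feats = [
            FeatureInterval("chr1", 5_000, 5_300, "+", "lnc_exon", "lncA",
                            "first"),
            FeatureInterval("chr1", 5_300, 5_500, "+", "lnc_intron",
                            "lncA", "unique"),
            FeatureInterval("chr1", 5_500, 5_800, "+", "lnc_exon", "lncA",
                            "last"),
        ]
        ar_start = 5_800 + ar_offset
        feats.append(FeatureInterval("chr1", ar_start, ar_start + 200,
                                     "+", "ancestral_repeat", "ar1",
                                     "unique"))
        if inside_intron:
            feats += [
                FeatureInterval("chr1", ar_start - 150, ar_start - 50,
                                "+", "cds_exon", "geneZ", "first"),
                FeatureInterval("chr1", ar_start - 50, ar_start + 300,
                                "+", "pc_intron", "geneZ", "unique"),
                FeatureInterval("chr1", ar_start + 300, ar_start + 400,
                                "+", "cds_exon", "geneZ", "last"),
            ]
        return AnnotationSet(feats)

    def test_ar_within_threshold_kept(self):
        ann = self.make(4_000)
        ars, retained = select_flanking_ancestral_repeats(
            ann, ProxySpec(kind="ancestral_repeat", max_distance=10_000))
        assert len(ars) == 1 and retained == ["lncA"]

    def test_ar_beyond_threshold_drops_locus(self):
        ann = self.make(12_000)
        ars, retained = select_flanking_ancestral_repeats(
            ann, ProxySpec(kind="ancestral_repeat", max_distance=10_000))
        assert ars == [] and retained == []

    def test_threshold_sweep_is_monotone(self):
        ann = self.make(7_000)
        sizes = []
        for dist in (5_000, 10_000, 20_000):
            ars, _ = select_flanking_ancestral_repeats(
                ann, ProxySpec(kind="ancestral_repeat",
                               max_distance=dist))
            sizes.append(len(ars))
        assert sizes == sorted(sizes)


class TestMasking:
    def _tracks(self, n, mismatch_positions):
        ref = np.frombuffer(b"A" * n, dtype="S1").copy()
        out = ref.copy()
        for p in mismatch_positions:
            out[p] = b"C"
        return ref, out

    def test_19_of_20_matches_masked(self):
        ref, out = self._tracks(20, [10])        # identity 0.95
        assert mask_conserved_elements(ref, out, [(0, 20)]) == []

    def test_17_of_20_matches_unmasked(self):
        ref, out = self._tracks(20, [5, 10, 15])  # identity 0.85
        assert mask_conserved_elements(ref, out, [(0, 20)]) == [(0, 20)]

    def test_fully_identical_flank_entirely_masked(self):
        ref, out = self._tracks(500, [])
        assert mask_conserved_elements(ref, out, [(0, 500)]) == []

    def test_masking_is_idempotent(self, rng):
        n = 2_000
        ref = np.frombuffer(bytes(rng.choice(list(b"ACGT"), n)),
                            dtype="S1").copy()
        out = ref.copy()
        flips = rng.choice(n, size=150, replace=False)
        out[flips] = b"N"
        out[out == b"N"] = b"T"
        once = mask_conserved_elements(ref, out, [(0, n)])
        twice = mask_conserved_elements(ref, out, once)
        assert once == twice

    def test_score_masker_drops_high_scores(self):
        cons = np.full(100, 0.1)
        cons[40:60] = 0.95
        spec = ProxySpec(mask_mode="score", score_threshold=0.8)
        out = mask_conserved_by_score(cons, [(0, 100)], spec)
        assert out == [(0, 40), (60, 100)]


class TestMatchedSampling:
    def test_zero_sites_gives_empty_sample(self, rng):
        out = sample_matched_sites(0, [(0, 2_000)], rng)
        assert len(out) == 0

    def test_same_seed_identical_sample(self):
        a = sample_matched_sites(50, [(0, 2_000)],
                                 np.random.default_rng(5))
        b = sample_matched_sites(50, [(0, 2_000)],
                                 np.random.default_rng(5))
        assert (a == b).all()

    def test_small_flank_rejected(self, rng):
        with pytest.raises(ValueError, match="minimum"):
            sample_matched_sites(10, [(0, 500)], rng)

    def test_sampling_is_uniform_without_replacement(self, rng):
        inclusion = np.zeros(1_000)
        n_rep, N = 2_000, 50
        for _ in range(n_rep):
            pos = sample_matched_sites(N, [(0, 1_000)], rng)
            assert len(np.unique(pos)) == N
            inclusion[pos] += 1
        p = N / 1_000
        se = np.sqrt(p * (1 - p) / n_rep)
        assert np.all(np.abs(inclusion / n_rep - p) < 5 * se)

    def test_matched_samples_pair_every_retained_locus(self, tiny_cohort):
        bundle, _ = tiny_cohort
        spec = ProxySpec(mask_mode="score")
        samples, exclusions = matched_neutral_samples(bundle, spec, seed=3)
        lnc = set(bundle.annotation.loci("lnc_exon"))
        assert {s.locus_id for s in samples} | \
            {e[0] for e in exclusions} == lnc
        for s in samples:
            n_exonic = sum(
                len(f) for f in bundle.annotation.gene_index[s.locus_id]
                if f.feature_class == "lnc_exon")
            assert s.n_sites == n_exonic == len(s.positions)
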