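"""Metagene decile profiles, control envelopes, single-site resampling and
splice-site information content."""

import numpy as np
import pytest

from lncsel import conservation
from lncsel.genomic import AnnotationSet, FeatureInterval


def features_on_track(lengths, fclass="lnc_exon", strand="+", gap=50,
                      start=0, chrom="chr1"):
    feats = []
    cur = start
    for i, ln in enumerate(lengths):
        feats.append(FeatureInterval(chrom, cur, cur + ln, strand, fclass,
                                     f"L{i}", "unique"))
        cur += ln + gap
    return feats


class TestMetagene:
    def test_constant_scores_give_flat_profile_with_zero_width_ci(self):
        feats = features_on_track([100] * 20)
        cons = {"chr1": np.full(3_000, 0.7)}
        prof = conservation.metagene_profile(feats, cons, n_boot=100,
                                             seed=0)
        t = prof.table
        assert np.allclose(t["median"], 0.7)
        assert np.allclose(t["ci_lower"], 0.7)
        assert np.allclose(t["ci_upper"], 0.7)

    def test_ten_bp_feature_deciles_equal_per_base_scores(self):
        feats = [FeatureInterval("chr1", 0, 10, "+", "lnc_exon", "L",
                                 "unique")]
        cons = {"chr1": np.arange(0.1, 1.05, 0.1)}
        prof = conservation.metagene_profile(feats, cons, n_boot=10,
                                             seed=0)
        assert np.allclose(prof.table["median"],
                           np.arange(0.1, 1.05, 0.1))

    def test_minus_strand_profile_is_reversed(self):
        scores = np.linspace(0, 1, 200)
        cons = {"chr1": scores}
        plus = [FeatureInterval("chr1", 0, 200, "+", "lnc_exon", "L",
                                "unique")]
        minus = [FeatureInterval("chr1", 0, 200, "-", "lnc_exon", "L",
                                 "unique")]
        p = conservation.metagene_profile(plus, cons, n_boot=10, seed=0)
        m = conservation.metagene_profile(minus, cons, n_boot=10, seed=0)
        assert np.allclose(p.table["median"].values,
                           m.table["median"].values[::-1])

    def test_short_features_dropped_and_logged(self):
        feats = features_on_track([5, 100])
        cons = {"chr1": np.full(1_000, 0.5)}
        prof = conservation.metagene_profile(feats, cons, n_boot=10,
                                             seed=0)
        assert len(prof.dropped) == 1

    def test_decile_medians_invariant_to_within_decile_shuffling(self, rng):
        scores = rng.random(300)
        cons = {"chr1": scores.copy()}
        feats = [FeatureInterval("chr1", 0, 300, "+", "lnc_exon", "L",
                                 "unique")]
        base = conservation.metagene_profile(feats, cons, n_boot=10,
                                             seed=0).table["median"].values
        shuffled = scores.copy()
        for d in range(10):
            seg = slice(d * 30, (d + 1) * 30)
            shuffled[seg] = rng.permutation(shuffled[seg])
        prof2 = conservation.metagene_profile(
            feats, {"chr1": shuffled}, n_boot=10, seed=0)
        assert np.allclose(base, prof2.table["median"].values)


class TestControlProfiles:
    def _annotation(self):
        feats = features_on_track([200] * 3, start=30_000, gap=3_000)
        return AnnotationSet(feats)

    def test_control_intervals_lie_away_from_genes(self, rng):
        ann = self._annotation()
        lens = {"chr1": 80_000}
        allowed = conservation.intergenic_space(ann, lens, 1_000)["chr1"]
        # by construction of the sampler every control interval must fit in
        # allowed space; verify the space itself excludes the 1 kb margins
        for f in ann.features:
            assert not allowed[f.start - 1_000:f.end + 1_000].any()

    def test_same_seed_identical_envelopes(self):
        ann = self._annotation()
        cons = {"chr1": np.random.default_rng(0).random(80_000)}
        kw = dict(n_sets=20, seed=7)
        b1 = conservation.control_profiles(ann, {"chr1": 80_000}, cons,
                                           [100, 150], **kw)
        b2 = conservation.control_profiles(ann, {"chr1": 80_000}, cons,
                                           [100, 150], **kw)
        assert np.allclose(b1["lower"], b2["lower"])
        assert np.allclose(b1["upper"], b2["upper"])

    def test_envelope_brackets_intergenic_distributed_targets(self):
        ann = self._annotation()
        cons = {"chr1": np.random.default_rng(3).random(80_000)}
        band = conservation.control_profiles(ann, {"chr1": 80_000}, cons,
                                             [120] * 10, n_sets=100,
                                             seed=1)
        assert (band["lower"] <= band["median"]).all()
        assert (band["median"] <= band["upper"]).all()


class TestSingleSite:
    def test_separated_distributions_give_p_zero(self):
        ex = features_on_track([50] * 5, "lnc_exon")
        intr = features_on_track([50] * 5, "lnc_intron", start=2_000)
        cons = {"chr1": np.concatenate([np.full(1_000, 0.9),
                                        np.full(9_000, 0.1)])}
        _, _, p = conservation.single_site_comparison(ex, intr, cons,
                                                      n_resamples=200,
                                                      seed=0)
        assert p == 0.0

    def test_identical_distributions_give_p_near_half(self):
        ex = features_on_track([50] * 10, "lnc_exon")
        intr = features_on_track([50] * 10, "lnc_intron", start=2_000)
        cons = {"chr1": np.random.default_rng(5).random(10_000)}
        _, _, p = conservation.single_site_comparison(ex, intr, cons,
                                                      n_resamples=1_000,
                                                      seed=0)
        # symmetric null: p within a generous binomial band around 0.5
        assert 0.40 <= p <= 0.60

    def test_single_locus_input_works(self):
        ex = [FeatureInterval("chr1", 0, 50, "+", "lnc_exon", "L",
                              "unique")]
        intr = [FeatureInterval("chr1", 60, 110, "+", "lnc_intron", "L",
                                "unique")]
        cons = {"chr1": np.full(200, 0.4)}
        em, im, p = conservation.single_site_comparison(ex, intr, cons,
                                                        n_resamples=10,
                                                        seed=0)
        assert np.allclose(em, 0.4) and np.allclose(im, 0.4)


class TestInformationContent:
    def test_uniform_column_has_full_information(self):
        assert conservation.column_information("GGGGG") == \
            pytest.approx(2.0)

    def test_mixed_column_entropy_by_hand(self):
        # p = (0.4, 0.2, 0.2, 0.2) -> H = 1.92193, IC = 0.07807
        ic = conservation.column_information(["A", "C", "G", "T", "A"])
        assert ic == pytest.approx(0.07807, abs=5e-6)

    def test_too_few_ungapped_bases_is_none(self):
        assert conservation.column_information(["A", "-", "-", "N"]) is None

    def test_identical_blocks_have_ic_two_everywhere(self):
        seq = "A" * 50 + "GT" + "C" * 50
        prof = conservation.splice_site_information([[seq] * 5], "5prime")
        assert np.allclose(prof.information, 2.0)

    def test_blocks_with_gapped_dinucleotide_are_skipped(self):
        good = "A" * 50 + "GT" + "C" * 50
        bad = "A" * 50 + "--" + "C" * 50
        prof = conservation.splice_site_information(
            [[good] * 5, [bad, bad, good, good, good][:5]], "5prime")
        assert prof.n_blocks >= 1

    def test_control_block_sampler_finds_dinucleotides(self, rng):
        track = np.frombuffer(b"ACGTGTAC" * 200, dtype="S1").copy()
        tracks = [{"chr1": track}, {"chr1": track.copy()}]
        blocks = conservation.control_splice_blocks(
            tracks, [("chr1", 0, 1_600)], "GT", 5, rng)
        assert blocks
        for blk in blocks:
            assert blk[0][50:52] == "GT"
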