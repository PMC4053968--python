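"""Synthetic cohort generator: frequency model, layout, truth, outgroups."""

import math

import numpy as np
import pytest

from lncsel import cohort
from lncsel.genomic import CLASS_CODE
from tests.conftest import small_cohort_config


class TestExpectedSfsDensity:
    def test_neutral_limit_is_one_over_q(self):
        assert cohort.expected_sfs_density(0.0, 0.25) == pytest.approx(4.0)

    def test_closed_form_at_gamma_minus_two(self):
        # independent spreadsheet-style evaluation of the stated formula
        g, q = -2.0, 0.5
        expected = ((1 - math.exp(-g * (1 - q)))
                    / ((1 - math.exp(-g)) * q * (1 - q)))
        assert cohort.expected_sfs_density(g, q) == pytest.approx(expected)

    def test_deleterious_density_shifts_to_low_frequency(self):
        ratios = [cohort.expected_sfs_density(g, 0.5)
                  / cohort.expected_sfs_density(g, 0.05)
                  for g in (0.0, -2.0, -10.0)]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            cohort.expected_sfs_density(0.0, 0.0)
        with pytest.raises(ValueError):
            cohort.expected_sfs_density(0.0, 1.0)

    def test_strongly_negative_gamma_is_finite(self):
        v = cohort.expected_sfs_density(-1000.0, 0.5)
        assert np.isfinite(v) and v >= 0


class TestAlleleCountModel:
    def test_neutral_count_pmf_is_one_over_k(self):
        I = cohort.allele_count_integrals(0.0, 20)
        expected = 1.0 / np.arange(1, 20)
        assert np.allclose(I, expected, rtol=1e-4)

    def test_neutral_singleton_fraction_matches_theory(self, rng):
        # binomial-sampling oracle around the 1/q density
        n, n_sites = 20, 5_000
        counts, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), n, n_sites, rng)
        a1 = sum(1.0 / i for i in range(1, n))
        p1 = (1.0 / 1) / a1
        observed = np.mean(counts == 1)
        se = math.sqrt(p1 * (1 - p1) / n_sites)
        assert abs(observed - p1) < 3 * se

    def test_selected_counts_skew_to_singletons(self, rng):
        neutral, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), 20, 4_000, rng)
        selected, gammas = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01, gamma=-10.0), 20, 4_000,
            rng)
        assert np.mean(selected == 1) > np.mean(neutral == 1)
        assert (gammas == -10.0).all()


class TestGenerateCohort:
    def test_same_seed_is_reproducible(self):
        cfg = small_cohort_config()
        b1, t1 = cohort.generate_cohort(cfg, 3)
        b2, t2 = cohort.generate_cohort(cfg, 3)
        assert t1.equals(t2)
        assert [(v.chrom, v.pos, v.alt_allele, v.allele_count)
                for v in b1.variants] == \
            [(v.chrom, v.pos, v.alt_allele, v.allele_count)
             for v in b2.variants]
        for c in b1.reference:
            assert (b1.reference[c] == b2.reference[c]).all()

    def test_zero_lncrnas_yields_no_lnc_features(self):
        cfg = small_cohort_config(n_lnc=0)
        bundle, _ = cohort.generate_cohort(cfg, 5)
        assert not any(f.feature_class.startswith("lnc_")
                       for f in bundle.annotation.features)

    def test_truth_ancestral_equals_reference_base(self, tiny_cohort):
        bundle, truth = tiny_cohort
        for row in truth.itertuples():
            ref_base = bundle.reference[row.chrom][row.pos - 1].decode()
            assert row.ancestral == ref_base

    def test_every_snp_has_exactly_one_truth_row(self, tiny_cohort):
        bundle, truth = tiny_cohort
        keys = list(zip(truth.chrom, truth.pos))
        assert len(keys) == len(set(keys)) == len(bundle.variants)

    def test_layout_overflow_raises_config_error(self):
        with pytest.raises(cohort.ConfigError):
            cohort.generate_cohort(
                small_cohort_config(chrom_length=5_000, n_genes=10), 1)

    def test_neutral_outgroup_divergence_matches_configured_d(self):
        cfg = small_cohort_config(chrom_length=100_000, n_genes=2, n_lnc=2,
                                  n_ar=2, d1=0.05, d2=0.10)
        bundle, _ = cohort.generate_cohort(cfg, 9)
        codes = bundle.annotation.class_codes("chr1")
        inter = np.flatnonzero(codes == CLASS_CODE["intergenic"])
        ref = bundle.reference["chr1"][inter]
        for og, d in zip(bundle.outgroups, (cfg.d1, cfg.d2)):
            p_obs = np.mean(og["chr1"][inter] != ref)
            p_exp = 0.75 * (1 - math.exp(-4 * d / 3))
            se = math.sqrt(p_exp * (1 - p_exp) / len(inter))
            assert abs(p_obs - p_exp) < 4 * se

    def test_deleterious_class_diverges_less_than_neutral(self):
        regimes = cohort._default_regimes()
        regimes["lnc_exon"] = cohort.SelectionRegime(theta=0.01,
                                                     gamma=-20.0)
        cfg = small_cohort_config(chrom_length=200_000, n_genes=6, n_lnc=12,
                                  n_ar=2, regimes=regimes, d1=0.08,
                                  d2=0.16)
        bundle, _ = cohort.generate_cohort(cfg, 13)
        codes = bundle.annotation.class_codes("chr1")
        ref = bundle.reference["chr1"]
        og = bundle.outgroups[0]["chr1"]
        inter = np.flatnonzero(codes == CLASS_CODE["intergenic"])
        lnc = np.flatnonzero(codes == CLASS_CODE["lnc_exon"])
        p_neu = np.mean(og[inter] != ref[inter])
        p_sel = np.mean(og[lnc] != ref[lnc])
        assert p_sel < p_neu

    def test_class_conditional_sfs_matches_density_oracle(self, rng):
        # KS distance between realized counts and the binomially sampled
        # expected spectrum shrinks with site count
        from scipy.stats import chisquare
        n = 20
        for gamma in (0.0, -5.0):
            counts, _ = cohort.sample_allele_counts(
                cohort.SelectionRegime(theta=0.01, gamma=gamma), n,
                20_000, rng)
            pmf = cohort.allele_count_integrals(gamma, n)
            pmf = pmf / pmf.sum()
            obs = np.bincount(counts, minlength=n)[1:n]
            stat, p = chisquare(obs, pmf * obs.sum())
            assert p > 1e-4


class TestTruthReport:
    def test_empty_truth_gives_header_only(self):
        import pandas as pd
        rep = cohort.truth_report(pd.DataFrame(
            columns=["feature_class", "gamma"]))
        assert list(rep.columns) == ["feature_class", "n_sites",
                                     "mean_gamma"]
        assert len(rep) == 0

    def test_counts_per_class(self):
        import pandas as pd
        truth = pd.DataFrame(dict(
            feature_class=["lnc_exon"] * 10 + ["pc_intron"] * 20,
            gamma=[-1.0] * 10 + [0.0] * 20))
        rep = cohort.truth_report(truth)
        out = dict(zip(rep.feature_class, rep.n_sites))
        assert out == {"lnc_exon": 10, "pc_intron": 20}
        means = dict(zip(rep.feature_class, rep.mean_gamma))
        assert means["lnc_exon"] < 0 and means["pc_intron"] == 0.0

    def test_fly_defaults_mean_gamma_signs(self, tiny_cohort):
        _, truth = tiny_cohort
        rep = cohort.truth_report(truth)
        means = dict(zip(rep.feature_class, rep.mean_gamma))
        assert means["lnc_exon"] < 0
        assert means["pc_intron"] == 0.0


class TestConfigYaml:
    def test_yaml_round_trip(self, tmp_path):
        cfg = small_cohort_config()
        path = str(tmp_path / "cfg.yaml")
        cohort.config_to_yaml(cfg, path)
        back = cohort.config_from_yaml(path)
        assert back == cfg
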