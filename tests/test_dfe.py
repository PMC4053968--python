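"""Wright-Fisher expected spectra, demography and gamma-DFE fitting.

The WF-grid route is checked against the independent closed-form density
route from the cohort module (the two oracles must meet), and parameter
recovery is exercised on simulated spectra.
"""

import numpy as np
import pytest

from lncsel import cohort, dfe
from lncsel.popgen import SFS, build_sfs


def density_route_folded(gamma, n):
    """Independent oracle: numeric integration of the equilibrium density
    against the binomial kernel, then folding."""
    I = cohort.allele_count_integrals(gamma, n)
    unf = I / I.sum()
    half = n // 2
    out = np.zeros(half)
    for i in range(1, n):
        out[min(i, n - i) - 1] += unf[i - 1]
    return out


EQ = dfe.Demography()


class TestExpectedSpectra:
    def test_neutral_matches_one_over_i(self):
        eng = dfe.SpectrumEngine(10)
        got = eng.folded(0.0, EQ)
        want = density_route_folded(0.0, 10)
        assert np.max(np.abs(got - want)) < 0.005      # < 0.5 pp per bin
        assert np.max(np.abs(got - want) / want) < 0.02

    @pytest.mark.parametrize("gamma", [-2.0, -10.0])
    def test_two_oracles_meet_within_two_percent(self, gamma):
        eng = dfe.SpectrumEngine(20)
        got = eng.folded(gamma, EQ)
        want = density_route_folded(gamma, 20)
        assert np.max(np.abs(got - want) / want) < 0.02

    def test_strong_selection_inflates_singleton_class(self):
        eng = dfe.SpectrumEngine(20)
        strong = eng.folded(-200.0, EQ)
        neutral = eng.folded(0.0, EQ)
        assert strong[0] > neutral[0]

    def test_expected_folded_sfs_sums_to_one(self, rng):
        for _ in range(8):
            model = dfe.DFEModel(
                demography=dfe.Demography(float(rng.uniform(0.5, 2.0)),
                                          float(rng.uniform(0.0, 0.2))),
                shape=float(rng.uniform(0.2, 2.0)),
                mean=float(rng.uniform(0.5, 50.0)))
            props = dfe.expected_folded_sfs(model, 10)
            assert props.sum() == pytest.approx(1.0, abs=1e-9)
            assert (props >= 0).all()

    def test_heavier_dfe_mean_raises_singleton_proportion(self):
        eng = dfe.SpectrumEngine(20)
        singles = []
        for mean in (0.5, 5.0, 50.0):
            model = dfe.DFEModel(shape=0.5, mean=mean)
            singles.append(dfe.expected_folded_sfs(model, 20, eng)[0])
        assert singles[0] < singles[1] < singles[2]

    def test_epoch_change_noop_at_equilibrium_params(self):
        f = dfe.equilibrium_sfs(200, 0.0)
        out = dfe.epoch_change(f, 200, 0.0, dfe.Demography(1.0, 0.0))
        assert (out == f).all()

    def test_likelihood_peaks_near_truth(self, rng):
        # self-consistency: average LL at the generating parameters beats
        # perturbed parameters on simulated spectra
        n, S = 20, 20_000
        eng = dfe.SpectrumEngine(n)
        truth_model = dfe.DFEModel(shape=0.5, mean=10.0)
        p_true = dfe.expected_folded_sfs(truth_model, n, eng)
        p_pert = dfe.expected_folded_sfs(
            dfe.DFEModel(shape=1.5, mean=1.0), n, eng)
        wins = 0
        for _ in range(10):
            counts = rng.multinomial(S, p_true)
            ll_true = np.sum(counts * np.log(p_true))
            ll_pert = np.sum(counts * np.log(p_pert))
            wins += ll_true > ll_pert
        assert wins >= 9


class TestFitDemography:
    def test_equilibrium_data_recovers_r_near_one(self, rng):
        counts, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), 20, 40_000, rng)
        fit = dfe.fit_demography(build_sfs(counts, 20, fold=True))
        assert 0.8 <= fit.params["r"] <= 1.25

    def test_singleton_excess_pushes_r_above_one(self, rng):
        n = 20
        eng = dfe.SpectrumEngine(n)
        props = eng.folded(0.0, EQ).copy()
        props[0] *= 2.0          # exaggerated singleton excess
        props /= props.sum()
        counts = rng.multinomial(30_000, props)
        fit = dfe.fit_demography(SFS(n, counts, True))
        assert fit.params["r"] > 1.0

    def test_flat_sfs_returns_finite_estimate(self):
        fit = dfe.fit_demography(SFS(20, np.full(10, 500), True))
        assert np.isfinite(fit.loglik)
        assert fit.params["r"] > 0


class TestFitDFE:
    def test_neutral_input_is_effectively_neutral(self, rng):
        counts, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), 20, 30_000, rng)
        fit = dfe.fit_dfe(build_sfs(counts, 20, fold=True), EQ)
        bins = dfe.nes_bin_proportions(fit.params["shape"],
                                       fit.params["mean"])
        assert bins[0] >= 0.90

    def test_degenerate_sfs_flagged_as_boundary(self):
        counts = np.zeros(10, dtype=int)
        counts[0] = 100
        fit = dfe.fit_dfe(SFS(20, counts, True), EQ)
        assert fit.params.get("boundary") is True


class TestNesBins:
    def test_exponential_closed_form(self):
        props = dfe.nes_bin_proportions(1.0, 1.0)
        assert props[0] == pytest.approx(1 - np.exp(-1), abs=1e-9)
        assert props[3] == pytest.approx(np.exp(-100), abs=1e-12)

    def test_normalization_for_random_parameters(self, rng):
        for _ in range(100):
            shape = float(rng.uniform(0.05, 5))
            mean = float(rng.uniform(0.01, 1_000))
            props = dfe.nes_bin_proportions(shape, mean)
            assert props.sum() == pytest.approx(1.0, abs=1e-9)
            assert (props >= 0).all()


class TestBootstrap:
    def _loci(self, rng, n_sites_per_locus=300, n_loci=4, gamma_dfe=None):
        regime = (cohort.SelectionRegime(theta=0.01, shape=0.5, mean=5.0)
                  if gamma_dfe is None else gamma_dfe)
        loci = {}
        for i in range(n_loci):
            counts, _ = cohort.sample_allele_counts(
                regime, 20, n_sites_per_locus, rng)
            loci[f"lnc{i}"] = counts.tolist()
        return loci

    def test_smoke_b2_and_ci_contains_point(self, rng):
        loci = self._loci(rng)
        neutral, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), 20, 2_000, rng)
        rep = dfe.bootstrap_dfe(loci, build_sfs(neutral, 20, fold=True),
                                20, B=2, seed=4, demography=EQ)
        assert rep.n_boot == 2
        assert rep.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_identical_report(self, rng):
        loci = self._loci(rng)
        neutral, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), 20, 2_000, rng)
        sfs_n = build_sfs(neutral, 20, fold=True)
        r1 = dfe.bootstrap_dfe(loci, sfs_n, 20, B=5, seed=9,
                               demography=EQ)
        r2 = dfe.bootstrap_dfe(loci, sfs_n, 20, B=5, seed=9,
                               demography=EQ)
        assert (r1.boot_mean == r2.boot_mean).all()
        assert (r1.ci_lower == r2.ci_lower).all()

    def test_b_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            dfe.bootstrap_dfe({"a": [1], "b": [2]},
                              SFS(20, np.full(10, 5), True), 20, B=1,
                              demography=EQ)

    def test_ci_width_shrinks_with_site_count(self, rng):
        neutral, _ = cohort.sample_allele_counts(
            cohort.SelectionRegime(theta=0.01), 20, 2_000, rng)
        sfs_n = build_sfs(neutral, 20, fold=True)
        small = dfe.bootstrap_dfe(self._loci(rng, 60), sfs_n, 20, B=10,
                                  seed=2, demography=EQ)
        large = dfe.bootstrap_dfe(self._loci(rng, 600), sfs_n, 20, B=10,
                                  seed=2, demography=EQ)
        width = lambda r: float(np.sum(r.ci_upper - r.ci_lower))  # noqa
        assert width(large) < width(small)
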