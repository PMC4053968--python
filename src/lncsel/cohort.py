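"""Synthetic two-species study generator.

Builds a complete fake cohort — genome, annotation (protein-coding genes
with small-intron quota, multi-exonic intergenic lncRNAs, ancestral
repeats), population SNPs with class-specific selection, two outgroups at
increasing divergence, per-site coverage/call quality, indels, per-base
conservation scores — together with full ground truth, so every downstream
stage can be exercised and scored without external data.

Sampling model: segregating-site allele counts are drawn from the
equilibrium frequency density of a mutation with scaled selection
coefficient gamma = 4*Ne*s,

    f(q) proportional to (1 - exp(-gamma (1-q))) /
                         ((1 - exp(-gamma)) q (1-q)),

integrated against the binomial sampling kernel at sample size n. At
gamma = 0 this reduces to the neutral 1/q density, whose sampled counts
follow P(k) = (1/k)/a_n exactly. Outgroup tracks diverge per class at rate
d * w(gamma) per branch, where w(gamma) = gamma/(1 - exp(-gamma)) is the
relative fixation probability (1 for neutral classes, < 1 for deleterious
ones), applied as a Jukes-Cantor end-state substitution probability so
double hits occur at a realistic rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom
from scipy.stats import gamma as _gamma_dist

from .genomic import (AnnotationSet, FeatureInterval, GenomeBundle,
                      IndelRecord, PopulationSite, flag_near_indels)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fly lnc_exon DFE calibrated so P(|Nes|<1) equals the reported 64.18%
# effectively-neutral fraction at shape 0.5
FLY_LNC_DFE_SHAPE = 0.5
FLY_LNC_DFE_MEAN = 1.1846


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SelectionRegime:
    """Per-class mutation/selection model.

    Either a point-mass scaled coefficient `gamma` (negative = deleterious,
    0 = neutral) or a gamma DFE over |Nes| (`shape`, `mean`, applied with
    negative sign). `theta` is the per-site population mutation rate
    4*Ne*mu; `ne_label` is the nominal Ne used only to report s =
    gamma/(4 Ne).
    """
    theta: float
    gamma: float = 0.0
    shape: float | None = None
    mean: float | None = None
    ne_label: float = 1.0e6

    def __post_init__(self):
        if self.theta <= 0:
            raise ConfigError("theta must be positive")
        if (self.shape is None) != (self.mean is None):
            raise ConfigError("gamma DFE needs both shape and mean")
        if self.shape is not None and (self.shape <= 0 or self.mean <= 0):
            raise ConfigError("gamma DFE shape and mean must be positive")

    @property
    def has_dfe(self) -> bool:
        return self.shape is not None


@dataclass(frozen=True)
class DemographyConfig:
    """Two-epoch option: recent size ratio r for duration t2 (N2 gens).

    Emulated only as a theta rescaling for recently arisen variation (a
    documented approximation; the spectrum shape stays at equilibrium).
    """
    r: float = 1.0
    t2: float = 0.0


def _default_regimes() -> dict:
    neutral = dict(theta=0.01, gamma=0.0)
    return {
        "cds_exon": SelectionRegime(theta=0.01, shape=0.4, mean=400.0),
        "utr5": SelectionRegime(theta=0.01, gamma=-1.0),
        "utr3": SelectionRegime(theta=0.01, gamma=-2.0),
        "pc_intron": SelectionRegime(**neutral),
        "lnc_exon": SelectionRegime(theta=0.01, shape=FLY_LNC_DFE_SHAPE,
                                    mean=FLY_LNC_DFE_MEAN),
        "lnc_intron": SelectionRegime(**neutral),
        "ancestral_repeat": SelectionRegime(**neutral),
        "intergenic": SelectionRegime(**neutral),
    }


def _default_cons_beta() -> dict:
    return {
        "cds_exon": (8.0, 2.0),
        "utr5": (3.0, 4.0),
        "utr3": (3.0, 4.0),
        "pc_intron": (1.0, 6.0),
        "lnc_exon": (3.0, 3.0),
        "lnc_intron": (1.0, 6.0),
        "ancestral_repeat": (1.0, 8.0),
        "intergenic": (1.0, 6.0),
    }


@dataclass
class CohortConfig:
    """Fly-like defaults: 162 haplotypes, theta ~ 1e-2, d_sim < d_yak."""
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 50
    n_lnc: int = 50
    n_ar: int = 50
    sample_n: int = 162
    d1: float = 0.06
    d2: float = 0.12
    regimes: dict = field(default_factory=_default_regimes)
    conservation_beta: dict = field(default_factory=_default_cons_beta)
    demography: DemographyConfig = field(default_factory=DemographyConfig)
    mean_coverage: float = 20.0
    frac_low_coverage: float = 0.01
    frac_low_called: float = 0.01
    min_called: int = 150
    qual_mean: float = 60.0
    qual_sd: float = 10.0
    indel_density: float = 2.0e-4
    small_intron_frac: float = 0.6

    def __post_init__(self):
        if self.sample_n < 4:
            raise ConfigError("need sample_n >= 4 haplotypes")
        # equality (incl. zero) is permitted so identical-outgroup
        # polarization checks can run; ordering nearest-first is enforced
        if not (0 <= self.d1 <= self.d2 < 0.75):
            raise ConfigError("need 0 <= d1 <= d2 < 0.75")


def human_config(**overrides) -> CohortConfig:
    """Human-like preset: ~neutral lncRNAs, low theta, chimp/macaque-style
    outgroup divergences, 348 haplotypes, near-indel + quality filters."""
    neutral = dict(theta=1.5e-3, gamma=0.0, ne_label=1.0e4)
    regimes = {
        "cds_exon": SelectionRegime(theta=1.5e-3, shape=0.2, mean=400.0,
                                    ne_label=1.0e4),
        "utr5": SelectionRegime(theta=1.5e-3, gamma=-0.5, ne_label=1.0e4),
        "utr3": SelectionRegime(theta=1.5e-3, gamma=-0.5, ne_label=1.0e4),
        "pc_intron": SelectionRegime(**neutral),
        "lnc_exon": SelectionRegime(**neutral),
        "lnc_intron": SelectionRegime(**neutral),
        "ancestral_repeat": SelectionRegime(**neutral),
        "intergenic": SelectionRegime(**neutral),
    }
    cons = _default_cons_beta() | {
        "lnc_exon": (1.0, 6.0), "lnc_intron": (1.0, 6.0)}
    # lower per-site diversity than the fly preset, so a larger genome is
    # simulated to keep class-wise SNP counts adequate for SFS inference
    kw = dict(sample_n=348, d1=0.012, d2=0.06, regimes=regimes,
              conservation_beta=cons, min_called=0,
              chrom_length=1_500_000, n_genes=80, n_lnc=80, n_ar=120)
    kw.update(overrides)
    return CohortConfig(**kw)


def fly_config(**overrides) -> CohortConfig:
    return CohortConfig(**overrides)


# ---------------------------------------------------------------------------
# frequency-spectrum mathematics

def expected_sfs_density(gamma: float, q) -> np.ndarray | float:
    """Relative equilibrium density of segregating frequency q under scaled
    selection gamma; the neutral limit (gamma = 0) is 1/q."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q must lie strictly inside (0, 1)")
    if abs(gamma) < 1e-9:
        out = 1.0 / q
    elif gamma > 0:
        out = (-np.expm1(-gamma * (1.0 - q)) /
               (-math.expm1(-gamma) * q * (1.0 - q)))
    else:
        # algebraically identical, stable for strongly negative gamma
        g = -gamma
        out = (np.exp(-g * q) * -np.expm1(-g * (1.0 - q)) /
               (-math.expm1(-g) * q * (1.0 - q)))
    return float(out) if out.ndim == 0 else out


_QUAD_POINTS = 4096


def _density_grid(gamma: float) -> tuple[np.ndarray, np.ndarray]:
    q = (np.arange(_QUAD_POINTS) + 0.5) / _QUAD_POINTS
    return q, expected_sfs_density(gamma, q)


_pmf_cache: dict = {}


def allele_count_integrals(gamma: float, n: int) -> np.ndarray:
    """I_k = integral of f_gamma(q) * Binom(n, k; q) dq for k = 1..n-1.

    Normalized so the neutral case gives I_k = 1/k exactly (up to
    quadrature error); sum(I_k) is then the class's relative segregating
    weight against a_n = sum 1/i.
    """
    key = (round(gamma, 8), n)
    if key not in _pmf_cache:
        q, dens = _density_grid(gamma)
        k = np.arange(1, n)
        B = _binom.pmf(k[None, :], n, q[:, None])
        _pmf_cache[key] = (dens / _QUAD_POINTS) @ B
    return _pmf_cache[key]


def segregating_weight(gamma: float, n: int) -> float:
    """Expected segregating-site yield relative to theta*L (neutral: a_n)."""
    return float(allele_count_integrals(gamma, n).sum())


def _dfe_gamma_grid(shape: float, mean: float, n: int,
                    n_points: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """|gamma| grid and *segregation-biased* weights for drawing the true
    gamma of an observed (segregating) SNP under a gamma DFE."""
    grid = np.logspace(-3, 3, n_points)
    edges = np.sqrt(grid[1:] * grid[:-1])
    cdf = _gamma_dist.cdf(edges, a=shape, scale=mean / shape)
    w_new = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    seg = np.array([segregating_weight(-g, n) for g in grid])
    w = w_new * seg
    return grid, w / w.sum(), w_new


def sample_allele_counts(regime: SelectionRegime, n: int, n_sites: int,
                         rng: np.random.Generator):
    """Draw (counts, gammas) for n_sites segregating SNPs under a regime."""
    if n_sites == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0))
    if regime.has_dfe:
        grid, w_seg, _ = _dfe_gamma_grid(regime.shape, regime.mean, n)
        gi = rng.choice(len(grid), size=n_sites, p=w_seg)
        gammas = -grid[gi]
        counts = np.empty(n_sites, dtype=np.int64)
        for g in np.unique(gammas):
            idx = np.flatnonzero(gammas == g)
            pmf = allele_count_integrals(g, n)
            pmf = pmf / pmf.sum()
            counts[idx] = rng.choice(np.arange(1, n), size=len(idx), p=pmf)
        return counts, gammas
    pmf = allele_count_integrals(regime.gamma, n)
    pmf = pmf / pmf.sum()
    counts = rng.choice(np.arange(1, n), size=n_sites, p=pmf)
    return counts, np.full(n_sites, float(regime.gamma))


def expected_site_yield(regime: SelectionRegime, n: int) -> float:
    """Expected segregating sites per bp (theta * relative weight)."""
    if regime.has_dfe:
        grid, _, w_new = _dfe_gamma_grid(regime.shape, regime.mean, n)
        seg = np.array([segregating_weight(-g, n) for g in grid])
        return regime.theta * float((w_new * seg).sum())
    return regime.theta * segregating_weight(regime.gamma, n)


def fixation_weight(gamma: float) -> float:
    """Relative fixation probability w = gamma / (1 - exp(-gamma))."""
    if abs(gamma) < 1e-9:
        return 1.0
    if gamma < -700:  # exp overflow; weight is numerically zero
        return 0.0
    return gamma / -math.expm1(-gamma)


def mean_fixation_weight(regime: SelectionRegime) -> float:
    if not regime.has_dfe:
        return fixation_weight(regime.gamma)
    grid = np.logspace(-3, 3, 64)
    edges = np.sqrt(grid[1:] * grid[:-1])
    cdf = _gamma_dist.cdf(edges, a=regime.shape,
                          scale=regime.mean / regime.shape)
    w_new = np.diff(np.concatenate(([0.0], cdf, [1.0])))
    return float(np.sum(w_new * [fixation_weight(-g) for g in grid]))


# ---------------------------------------------------------------------------
# genome layout

def _make_gene(chrom, pos, lid, rng, cfg) -> tuple[list[FeatureInterval],
                                                   int]:
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(2, 5))
    ex_lens = (rng.integers(50, 101, size=n_ex) * 3).tolist()
    in_lens = []
    for _ in range(n_ex - 1):
        if rng.random() < cfg.small_intron_frac:
            in_lens.append(int(rng.integers(50, 87)))
        else:
            in_lens.append(int(rng.integers(200, 800)))
    utr5_len, utr3_len = 150, 200
    feats = []
    cur = pos
    blocks: list[tuple[str, int]] = [("utr5", utr5_len)]
    for i, el in enumerate(ex_lens):
        blocks.append(("cds_exon", el))
        if i < n_ex - 1:
            blocks.append(("pc_intron", in_lens[i]))
    blocks.append(("utr3", utr3_len))
    if strand == "-":
        blocks = blocks[::-1]
    genomic = []
    for kind, ln in blocks:
        genomic.append((kind, cur, cur + ln))
        cur += ln
    # ordinals in transcript orientation
    tx = genomic if strand == "+" else genomic[::-1]
    for kind_set in (("cds_exon",), ("pc_intron",)):
        items = [g for g in tx if g[0] in kind_set]
        for i, (kind, s, e) in enumerate(items):
            if len(items) == 1:
                o = "unique"
            elif i == 0:
                o = "first"
            elif i == len(items) - 1:
                o = "last"
            else:
                o = "middle"
            feats.append(FeatureInterval(chrom, s, e, strand, kind, lid, o))
    for kind, s, e in tx:
        if kind in ("utr5", "utr3"):
            feats.append(FeatureInterval(chrom, s, e, strand, kind, lid,
                                         "unique"))
    return feats, cur


def _make_lnc(chrom, pos, lid, rng) -> tuple[list[FeatureInterval], int]:
    strand = "+" if rng.random() < 0.5 else "-"
    n_ex = int(rng.integers(3, 5))
    ex_lens = rng.integers(200, 401, size=n_ex).tolist()
    in_lens = rng.integers(300, 701, size=n_ex - 1).tolist()
    cur = pos
    genomic = []
    for i, el in enumerate(ex_lens):
        genomic.append(("lnc_exon", cur, cur + el))
        cur += el
        if i < n_ex - 1:
            genomic.append(("lnc_intron", cur, cur + in_lens[i]))
            cur += in_lens[i]
    tx = genomic if strand == "+" else genomic[::-1]
    feats = []
    for kind_set in (("lnc_exon",), ("lnc_intron",)):
        items = [g for g in tx if g[0] in kind_set]
        for i, (kind, s, e) in enumerate(items):
            if len(items) == 1:
                o = "unique"
            elif i == 0:
                o = "first"
            elif i == len(items) - 1:
                o = "last"
            else:
                o = "middle"
            feats.append(FeatureInterval(chrom, s, e, strand, kind, lid, o))
    return feats, cur


def layout_annotation(cfg: CohortConfig,
                      rng: np.random.Generator) -> AnnotationSet:
    """Place gene / lncRNA / ancestral-repeat cassettes with >= 1 kb
    intergenic flanks, spreading counts over the chromosomes."""
    feats: list[FeatureInterval] = []
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    counters = dict(gene=0, lnc=0, ar=0)
    per_chrom_units = math.ceil(max(cfg.n_genes, cfg.n_lnc, cfg.n_ar)
                                / cfg.n_chromosomes)
    for chrom in chroms:
        cur = int(rng.integers(1000, 2000))
        for _ in range(per_chrom_units):
            gap = lambda: int(rng.integers(1000, 2600))  # noqa: E731
            if counters["gene"] < cfg.n_genes:
                lid = f"gene{counters['gene']:04d}"
                fs, cur = _make_gene(chrom, cur, lid, rng, cfg)
                feats.extend(fs)
                counters["gene"] += 1
                cur += gap()
            if counters["lnc"] < cfg.n_lnc:
                lid = f"lnc{counters['lnc']:04d}"
                fs, cur = _make_lnc(chrom, cur, lid, rng)
                feats.extend(fs)
                counters["lnc"] += 1
                cur += gap()
            if counters["ar"] < cfg.n_ar:
                lid = f"ar{counters['ar']:04d}"
                ln = int(rng.integers(300, 601))
                feats.append(FeatureInterval(chrom, cur, cur + ln, "+",
                                             "ancestral_repeat", lid,
                                             "unique"))
                counters["ar"] += 1
                cur += gap()
            if cur > cfg.chrom_length - 12_000:
                break
        if cur > cfg.chrom_length:
            raise ConfigError(
                f"layout overflows {chrom} ({cur} > {cfg.chrom_length}); "
                "reduce feature counts or lengthen chromosomes")
    if (counters["gene"] < cfg.n_genes or counters["lnc"] < cfg.n_lnc
            or counters["ar"] < cfg.n_ar):
        raise ConfigError("layout could not place all requested features; "
                          "lengthen chromosomes")
    return AnnotationSet(feats)


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(cfg: CohortConfig, seed: int):
    """Simulate the full study; returns (GenomeBundle, truth DataFrame).

    Deterministic given (cfg, seed). Truth rows carry, per SNP, the true
    ancestral allele (always the pre-mutation reference base), the feature
    class it was drawn for, and its scaled selection coefficient.
    """
    rng = np.random.default_rng(seed)
    annotation = layout_annotation(cfg, rng)
    chromosomes = [(f"chr{i + 1}", cfg.chrom_length)
                   for i in range(cfg.n_chromosomes)]
    lens = dict(chromosomes)
    annotation.build_index(lens)

    reference = {c: _BASES[rng.integers(0, 4, size=n)].copy()
                 for c, n in chromosomes}

    from .genomic import CLASS_CODE, FEATURE_CLASSES
    theta_scale = 1.0 + (cfg.demography.r - 1.0) * min(cfg.demography.t2,
                                                       1.0)
    n = cfg.sample_n
    variants: list[PopulationSite] = []
    truth_rows = []
    cons = {c: np.empty(L) for c, L in chromosomes}
    # class-wise per-base masks reused for SNPs, outgroups and scores
    for chrom, L in chromosomes:
        codes = annotation.class_codes(chrom)
        for fclass in FEATURE_CLASSES:
            pos_c = np.flatnonzero(codes == CLASS_CODE[fclass])
            if len(pos_c) == 0:
                continue
            a, b = cfg.conservation_beta[fclass]
            cons[chrom][pos_c] = rng.beta(a, b, size=len(pos_c))
            regime = cfg.regimes[fclass]
            lam = expected_site_yield(regime, n) * len(pos_c) * theta_scale
            n_snp = min(int(rng.poisson(lam)), len(pos_c))
            if n_snp == 0:
                continue
            snp_pos = rng.choice(pos_c, size=n_snp, replace=False)
            snp_pos.sort()
            counts, gammas = sample_allele_counts(regime, n, n_snp, rng)
            anc = reference[chrom][snp_pos]
            shift = rng.integers(1, 4, size=n_snp)
            anc_idx = np.searchsorted(_BASES, anc)
            der = _BASES[(anc_idx + shift) % 4]
            cov = rng.poisson(cfg.mean_coverage, size=n_snp)
            low_cov = rng.random(n_snp) < cfg.frac_low_coverage
            cov[low_cov] = rng.integers(0, 10, size=int(low_cov.sum()))
            qual = rng.normal(cfg.qual_mean, cfg.qual_sd, size=n_snp)
            low_called = rng.random(n_snp) < cfg.frac_low_called
            n_called = np.full(n_snp, n)
            if cfg.min_called > 0:
                n_called[low_called] = rng.integers(
                    max(4, cfg.min_called - 50), cfg.min_called,
                    size=int(low_called.sum()))
            for i in range(n_snp):
                k = int(min(counts[i], n_called[i] - 1))
                variants.append(PopulationSite(
                    chrom, int(snp_pos[i]) + 1, anc[i].decode(),
                    der[i].decode(), k, int(n_called[i]),
                    coverage=int(cov[i]), qual=float(qual[i])))
                truth_rows.append(dict(
                    chrom=chrom, pos=int(snp_pos[i]) + 1,
                    ancestral=anc[i].decode(), derived=der[i].decode(),
                    feature_class=fclass, gamma=float(gammas[i]),
                    s=float(gammas[i]) / (4.0 * regime.ne_label)))

    # outgroup tracks: JC end-state substitution per branch, class-scaled
    outgroups = []
    for d in (cfg.d1, cfg.d2):
        og = {c: reference[c].copy() for c, _ in chromosomes}
        for chrom, L in chromosomes:
            codes = annotation.class_codes(chrom)
            p_sub = np.empty(L)
            for fclass in FEATURE_CLASSES:
                m = codes == CLASS_CODE[fclass]
                if not m.any():
                    continue
                w = mean_fixation_weight(cfg.regimes[fclass])
                p_sub[m] = 0.75 * -math.expm1(-4.0 * d * w / 3.0)
            hit = np.flatnonzero(rng.random(L) < p_sub)
            if len(hit):
                idx = np.searchsorted(_BASES, og[chrom][hit])
                og[chrom][hit] = _BASES[
                    (idx + rng.integers(1, 4, size=len(hit))) % 4]
        outgroups.append(og)

    # indels (positions only matter; emitted as 2-bp deletions)
    indels = []
    for chrom, L in chromosomes:
        n_ind = rng.poisson(cfg.indel_density * L)
        for p in np.sort(rng.choice(L - 2, size=n_ind, replace=False)):
            ref2 = reference[chrom][p:p + 2].tobytes().decode()
            indels.append(IndelRecord(chrom, int(p) + 1, ref2, ref2[0]))
    flag_near_indels(variants, indels)

    bundle = GenomeBundle(chromosomes, reference, outgroups, cons,
                          variants, annotation, indels, sample_size=n)
    truth = pd.DataFrame(truth_rows, columns=[
        "chrom", "pos", "ancestral", "derived", "feature_class", "gamma",
        "s"])
    bundle.validate()
    return bundle, truth


def truth_report(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-feature-class site counts and mean selection coefficients."""
    cols = ["feature_class", "n_sites", "mean_gamma"]
    if truth.empty:
        return pd.DataFrame(columns=cols)
    g = truth.groupby("feature_class")["gamma"].agg(["size", "mean"])
    out = g.reset_index()
    out.columns = cols
    return out


# ---------------------------------------------------------------------------
# two-species layout for positional-equivalence analyses

def generate_species_pair(n_pe: int = 30, n_control: int = 30,
                          n_unanchored: int = 5, seed: int = 0,
                          spacing: int = 20_000):
    """Two annotation sets with planted positionally-equivalent lncRNAs.

    Each unit holds one protein-coding anchor and one lncRNA on a chosen
    side/orientation; species B mirrors species A for PE units and flips
    side and/or orientation for control units. Anchors are 1-to-1
    orthologous except for `n_unanchored` units left out of the map.
    Returns (annot_A, annot_B, ortholog_map, truth DataFrame).
    """
    rng = np.random.default_rng(seed)
    feats_a, feats_b = [], []
    orth = {}
    rows = []
    total = n_pe + n_control + n_unanchored
    for i in range(total):
        base_a = 2000 + i * spacing
        base_b = 2000 + i * spacing
        g_strand = "+" if rng.random() < 0.5 else "-"
        side = "5prime_of_gene" if rng.random() < 0.5 else "3prime_of_gene"
        rel = "same" if rng.random() < 0.5 else "opposite"
        kind = ("pe" if i < n_pe else
                "control" if i < n_pe + n_control else "unanchored")
        if kind == "control":
            flip_side = rng.random() < 0.7
            side_b = ({"5prime_of_gene": "3prime_of_gene",
                       "3prime_of_gene": "5prime_of_gene"}[side]
                      if flip_side else side)
            rel_b = rel if flip_side else (
                "same" if rel == "opposite" else "opposite")
        else:
            side_b, rel_b = side, rel
        for (feats, base, sd, rl, sp) in ((feats_a, base_a, side, rel, "A"),
                                          (feats_b, base_b, side_b, rel_b,
                                           "B")):
            gid = f"{sp}gene{i:03d}"
            lid = f"{sp}lnc{i:03d}"
            gene_len, lnc_len, gap = 3000, 1200, 2000
            upstream = (sd == "5prime_of_gene") == (g_strand == "+")
            if upstream:
                lnc_start, gene_start = base, base + lnc_len + gap
            else:
                gene_start, lnc_start = base, base + gene_len + gap
            l_strand = g_strand if rl == "same" else (
                "-" if g_strand == "+" else "+")
            feats.append(FeatureInterval(
                "chr1", gene_start, gene_start + gene_len, g_strand,
                "cds_exon", gid, "unique"))
            half = lnc_len // 2 - 100
            feats.append(FeatureInterval(
                "chr1", lnc_start, lnc_start + half, l_strand, "lnc_exon",
                lid, "first" if l_strand == "+" else "last"))
            feats.append(FeatureInterval(
                "chr1", lnc_start + half, lnc_start + half + 200, l_strand,
                "lnc_intron", lid, "unique"))
            feats.append(FeatureInterval(
                "chr1", lnc_start + half + 200, lnc_start + lnc_len,
                l_strand, "lnc_exon", lid,
                "last" if l_strand == "+" else "first"))
        if kind != "unanchored":
            orth[f"Agene{i:03d}"] = f"Bgene{i:03d}"
        rows.append(dict(unit=i, kind=kind, lnc_a=f"Alnc{i:03d}",
                         lnc_b=f"Blnc{i:03d}", side_a=side, rel_a=rel,
                         side_b=side_b, rel_b=rel_b))
    annot_a = AnnotationSet(feats_a, orth)
    annot_b = AnnotationSet(feats_b, {v: k for k, v in orth.items()})
    return annot_a, annot_b, orth, pd.DataFrame(rows)


def config_to_yaml(cfg: CohortConfig, path: str) -> None:
    import yaml
    d = asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path: str) -> CohortConfig:
    import yaml
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["regimes"] = {k: SelectionRegime(**v)
                    for k, v in d.get("regimes", {}).items()}
    d["conservation_beta"] = {k: tuple(v) for k, v in
                              d.get("conservation_beta", {}).items()}
    d["demography"] = DemographyConfig(**d.get("demography", {}))
    return CohortConfig(**d)
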