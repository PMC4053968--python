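"""End-to-end orchestration: simulate -> polarize -> proxies -> popgen ->
selection tests -> DFE -> conservation -> synteny -> report.

Every random draw derives from one run seed fanned out to named per-stage
substreams, so reruns with the same config are identical and stages can be
toggled without perturbing each other.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__, cohort, conservation, dfe, proxies, seltests
from . import polarize as pol
from . import popgen, synteny
from .genomic import CLASS_CODE, write_bundle

STAGES = ("simulate", "polarize", "proxies", "popgen", "tests", "dfe",
          "conserve", "synteny", "report")

# paper-scale resample counts; the ci scale divides these by 10
DEFAULT_COUNTS = dict(metagene_boot=10_000, control_sets=1_000,
                      single_site_resamples=1_000, dfe_boot=200)


@dataclass
class RunConfig:
    outdir: str
    preset: str = "fly-like"          # fly-like | human-like
    seed: int = 0
    scale: str = "default"            # default | ci
    stages: tuple = STAGES
    cohort_overrides: dict = field(default_factory=dict)
    polarize_policy: str = "strict"
    input_paths: dict | None = None   # alternative to simulation

    def __post_init__(self):
        if self.preset not in ("fly-like", "human-like"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if (self.input_paths is not None) and self.cohort_overrides:
            raise ValueError("give input paths or a synthetic config, "
                             "not both")

    def counts(self) -> dict:
        c = dict(DEFAULT_COUNTS)
        if self.scale == "ci":
            c = {k: max(2, v // 10) for k, v in c.items()}
        return c


def stage_seed(run_seed: int, stage: str) -> int:
    """Named substream: stable hash of the stage name mixed with the run
    seed, kept below 2**31."""
    return (run_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _class_positions(bundle, fclass: str) -> dict[str, np.ndarray]:
    out = {}
    for chrom, _L in bundle.chromosomes:
        codes = bundle.annotation.class_codes(chrom)
        out[chrom] = np.flatnonzero(codes == CLASS_CODE[fclass])
    return out


def _sites_at(sites, positions: dict[str, np.ndarray]):
    sets = {c: set(p.tolist()) for c, p in positions.items()}
    return [s for s in sites if (s.pos - 1) in sets.get(s.chrom, ())]


def _divergence_count(bundle, positions: dict[str, np.ndarray],
                      og_index: int = 0):
    aligned = diffs = 0
    for chrom, pos in positions.items():
        if len(pos) == 0:
            continue
        d = popgen.jc_divergence(bundle.reference[chrom],
                                 bundle.outgroups[og_index][chrom], pos)
        aligned += d.aligned_sites
        diffs += d.differences
    return aligned, diffs


def run_pipeline(config: RunConfig) -> dict:
    os.makedirs(config.outdir, exist_ok=True)
    manifest = []
    report: dict = {"preset": config.preset, "seed": config.seed}
    counts = config.counts()
    fly = config.preset == "fly-like"

    def record(stage, **info):
        manifest.append(dict(stage=stage, seed=stage_seed(config.seed,
                                                          stage),
                             version=__version__, **info))

    # --- simulate ---------------------------------------------------------
    if config.input_paths is not None:
        from .genomic import load_bundle
        bundle = load_bundle(config.input_paths)
        truth = None
        record("simulate", skipped="external inputs supplied",
               inputs=sorted(map(str, config.input_paths.values())))
    else:
        maker = cohort.fly_config if fly else cohort.human_config
        ccfg = maker(**config.cohort_overrides)
        bundle, truth = cohort.generate_cohort(
            ccfg, stage_seed(config.seed, "simulate"))
        paths = write_bundle(bundle, os.path.join(config.outdir, "cohort"))
        truth.to_csv(os.path.join(config.outdir, "cohort", "truth.tsv"),
                     sep="\t", index=False)
        cohort.truth_report(truth).to_csv(
            os.path.join(config.outdir, "cohort", "truth_report.tsv"),
            sep="\t", index=False)
        record("simulate", inputs=[], outputs=sorted(
            os.path.relpath(p, config.outdir) for v in paths.values()
            for p in (v if isinstance(v, list) else [v])))
    n = bundle.sample_size
    report["n_haplotypes"] = n
    report["n_raw_snps"] = len(bundle.variants)

    # --- polarize ---------------------------------------------------------
    profile = pol.filter_profile("fly" if fly else "human")
    kept, tally = pol.filter_sites(bundle.variants, profile)
    kept = [s for s in kept if s.n_called == n]  # fixed-n stratum
    polarised, n_ambig = pol.polarize_all(kept, bundle.outgroups,
                                          policy=config.polarize_policy)
    pd.DataFrame([dict(reason=k, count=v) for k, v in sorted(
        tally.items())]).to_csv(
        os.path.join(config.outdir, "filter_tally.tsv"), sep="\t",
        index=False)
    anc = {(s.chrom, s.pos): s.ancestral_allele for s in polarised}
    from .genomic import write_vcf
    write_vcf(polarised, [], os.path.join(config.outdir, "polarised.vcf"),
              bundle.chromosomes, ancestral=anc)
    report["polarize"] = dict(kept=len(kept), ambiguous=n_ambig,
                              polarised=len(polarised), tally=tally)
    record("polarize", profile=profile.name,
           policy=config.polarize_policy)

    # position lookup for classes
    by_pos = {(s.chrom, s.pos - 1): s for s in polarised}

    # --- proxies ----------------------------------------------------------
    # score-based flank masking: the synthetic outgroups are too close for
    # 20-nt window identity to separate conserved elements from background
    pspec = proxies.ProxySpec(max_distance=5_000 if fly else 10_000,
                              mask_mode="score")
    small_introns = proxies.select_small_introns(bundle.annotation, pspec)
    flank_ars, ar_retained = proxies.select_flanking_ancestral_repeats(
        bundle.annotation, proxies.ProxySpec(kind="ancestral_repeat",
                                             max_distance=10_000))
    matched, excl = proxies.matched_neutral_samples(
        bundle, pspec, seed=stage_seed(config.seed, "proxies"))
    from .genomic import write_annotation_bed
    write_annotation_bed(small_introns, os.path.join(
        config.outdir, "small_introns.bed"))
    write_annotation_bed(flank_ars, os.path.join(
        config.outdir, "flanking_ars.bed"))
    pd.DataFrame(excl, columns=["locus", "reason"]).to_csv(
        os.path.join(config.outdir, "proxy_exclusions.tsv"), sep="\t",
        index=False)
    report["proxies"] = dict(small_introns=len(small_introns),
                             flanking_ars=len(flank_ars),
                             matched_loci=len(matched),
                             excluded_loci=len(excl))
    record("proxies", spec=dict(max_distance=pspec.max_distance))

    neutral_positions: dict[str, np.ndarray] = {}
    for msamp in matched:
        cur = neutral_positions.get(msamp.chrom, np.empty(0, np.int64))
        neutral_positions[msamp.chrom] = np.concatenate(
            [cur, msamp.positions])
    for c in neutral_positions:
        neutral_positions[c] = np.unique(neutral_positions[c])

    proxy_class = "pc_intron" if fly else "ancestral_repeat"
    proxy_positions: dict[str, np.ndarray] = {}
    proxy_feats = small_introns if fly else flank_ars
    for f in proxy_feats:
        cur = proxy_positions.get(f.chrom, np.empty(0, np.int64))
        proxy_positions[f.chrom] = np.concatenate(
            [cur, np.arange(f.start, f.end)])
    for c in proxy_positions:
        proxy_positions[c] = np.unique(proxy_positions[c])

    # --- popgen -----------------------------------------------------------
    rows = []
    class_sites: dict[str, list] = {}
    for fclass in ("cds_exon", "pc_intron", "lnc_exon", "lnc_intron",
                   "ancestral_repeat"):
        feats_by_locus: dict[str, list] = {}
        for f in bundle.annotation.features:
            if f.feature_class == fclass and f.locus_id:
                feats_by_locus.setdefault(f.locus_id, []).append(f)
        for lid, fs in sorted(feats_by_locus.items()):
            pos = {c: np.array(sorted({p for f in fs if f.chrom == c
                                       for p in range(f.start, f.end)}),
                               dtype=np.int64)
                   for c in {f.chrom for f in fs}}
            sites = [by_pos[(c, p)] for c, arr in pos.items()
                     for p in arr.tolist() if (c, p) in by_pos]
            L = int(sum(len(a) for a in pos.values()))
            if L == 0:
                continue
            summ = popgen.summarize_region(sites, L, n)
            aligned, diffs = _divergence_count(bundle, pos)
            k = (popgen.jc_correct(diffs / aligned) if aligned else
                 float("nan"))
            rows.append(dict(feature_class=fclass, locus=lid, L=L,
                             S=summ.S, piT=summ.piT, thetaW=summ.thetaW,
                             tajD=summ.tajD, k=k))
            class_sites.setdefault(fclass, []).extend(sites)
    # neutral proxy strata (trimmed small introns / flanking ARs, matched
    # flank samples) as their own rows
    proxy_sites = _sites_at(polarised, proxy_positions)
    L_proxy = int(sum(len(v) for v in proxy_positions.values()))
    if L_proxy:
        summ = popgen.summarize_region(proxy_sites, L_proxy, n)
        aligned, diffs = _divergence_count(bundle, proxy_positions)
        rows.append(dict(
            feature_class="small_intron" if fly else "flanking_ar",
            locus="pooled", L=L_proxy, S=summ.S, piT=summ.piT,
            thetaW=summ.thetaW, tajD=summ.tajD,
            k=popgen.jc_correct(diffs / aligned) if aligned else
            float("nan")))
    locus_table = pd.DataFrame(rows)
    locus_table.to_csv(os.path.join(config.outdir, "popgen_loci.tsv"),
                       sep="\t", index=False)
    summary_rows = []
    for fclass, grp in locus_table.groupby("feature_class"):
        entry = dict(feature_class=fclass, n_loci=len(grp))
        for col in ("piT", "thetaW", "tajD", "k"):
            m, sd = popgen.mean_sd(grp[col])
            entry[col] = m
            entry[col + "_sd"] = sd
        summary_rows.append(entry)
    class_summary = pd.DataFrame(summary_rows)
    class_summary.to_csv(os.path.join(config.outdir,
                                      "popgen_classes.tsv"),
                         sep="\t", index=False)
    report["popgen"] = {r["feature_class"]: dict(tajD=r["tajD"],
                                                 piT=r["piT"], k=r["k"])
                        for r in summary_rows}
    record("popgen", n=n)

    # --- selection tests --------------------------------------------------
    tests = []
    lnc_exon_sites = class_sites.get("lnc_exon", [])
    lnc_intron_sites = class_sites.get("lnc_intron", [])
    matched_sites = _sites_at(polarised, neutral_positions)

    def mk_against_neutral(label, focal_sites, focal_positions):
        L_focal = int(sum(len(v) for v in focal_positions.values()))
        aligned_f, div_f = _divergence_count(bundle, focal_positions)
        aligned_n, div_n = _divergence_count(bundle, neutral_positions)
        try:
            table = seltests.MKTable(len(focal_sites), div_f,
                                     len(matched_sites), div_n)
            chi2, df, p = seltests.mk_test(table)
        except ValueError as err:
            tests.append(dict(family="mk", test=label, statistic=np.nan,
                              p=np.nan, note=str(err)))
            return
        tests.append(dict(family="mk", test=label, statistic=chi2, p=p,
                          note=f"P/D focal {len(focal_sites)}/{div_f}, "
                               f"neutral {len(matched_sites)}/{div_n}"))

    lnc_exon_positions = _class_positions(bundle, "lnc_exon")
    lnc_intron_positions = _class_positions(bundle, "lnc_intron")
    if matched_sites:
        mk_against_neutral("lnc_exon_vs_matched_neutral", lnc_exon_sites,
                           lnc_exon_positions)
        mk_against_neutral("lnc_intron_vs_matched_neutral",
                           lnc_intron_sites, lnc_intron_positions)

    proxy_label = "small_introns" if fly else "flanking_ars"
    daf_comparators = []
    if proxy_sites:
        daf_comparators.append((proxy_label, proxy_sites))
    if matched_sites:
        daf_comparators.append(("matched_neutral", matched_sites))
    for neutral_label, neutral_daf_sites in daf_comparators:
        if not lnc_exon_sites:
            break
        focal_daf = [s.daf for s in lnc_exon_sites]
        neutral_daf = [s.daf for s in neutral_daf_sites]
        cmp_all = seltests.compare_daf_spectra(focal_daf, neutral_daf)
        tests.append(dict(family="daf",
                          test=f"lnc_exon_vs_{neutral_label}",
                          statistic=cmp_all.ks_statistic, p=cmp_all.p_value,
                          note=f"prop DAF<=0.01 focal "
                               f"{cmp_all.prop_low_focal:.4f} neutral "
                               f"{cmp_all.prop_low_neutral:.4f}"))
        for mclass in ("GCtoAT", "ATtoGC"):
            fd = [s.daf for s in lnc_exon_sites
                  if seltests.mutation_class(s.ancestral_allele,
                                             s.derived_allele) == mclass]
            nd = [s.daf for s in neutral_daf_sites
                  if seltests.mutation_class(s.ancestral_allele,
                                             s.derived_allele) == mclass]
            if fd and nd:
                c = seltests.compare_daf_spectra(fd, nd)
                tests.append(dict(
                    family="daf",
                    test=f"lnc_exon_vs_{neutral_label}_{mclass}",
                    statistic=c.ks_statistic, p=c.p_value,
                    note=f"n focal {len(fd)}, neutral {len(nd)}"))
    # Kruskal-Wallis on per-locus Tajima's D across classes
    kw_groups = [grp["tajD"].dropna().values
                 for _c, grp in locus_table.groupby("feature_class")
                 if grp["tajD"].notna().sum() > 0]
    if len(kw_groups) >= 2:
        h, df_kw, p_kw = seltests.kruskal_wallis(*kw_groups)
        tests.append(dict(family="kruskal", test="tajD_across_classes",
                          statistic=h, p=p_kw, note=f"df={df_kw}"))
    # lncRNA-vs-neutral-only contrast (protein-coding constraint excluded)
    lnc_classes = ("lnc_exon", "lnc_intron",
                   "small_intron" if fly else "flanking_ar",
                   "ancestral_repeat")
    kw_lnc = [grp["tajD"].dropna().values
              for c, grp in locus_table.groupby("feature_class")
              if c in lnc_classes and grp["tajD"].notna().sum() > 0]
    if len(kw_lnc) >= 2:
        h, df_kw, p_kw = seltests.kruskal_wallis(*kw_lnc)
        tests.append(dict(family="kruskal", test="tajD_lnc_vs_neutral",
                          statistic=h, p=p_kw, note=f"df={df_kw}"))
    test_table = pd.DataFrame(tests)
    if len(test_table):
        test_table["p_adjusted"] = seltests.bonferroni(
            test_table["p"].fillna(1.0).values)
    test_table.to_csv(os.path.join(config.outdir, "selection_tests.tsv"),
                      sep="\t", index=False)
    report["tests"] = test_table.to_dict(orient="records")
    record("tests", family_size=len(test_table))

    # --- DFE --------------------------------------------------------------
    dfe_report = {}
    neutral_counts = [s.derived_count for s in matched_sites]
    sel_by_locus: dict[str, list[int]] = {}
    for s in lnc_exon_sites:
        _cl, lid, _o = bundle.annotation.site_class(s.chrom, s.pos - 1)
        sel_by_locus.setdefault(lid or "unknown", []).append(
            s.derived_count)
    if len(neutral_counts) >= 50 and sum(map(len,
                                             sel_by_locus.values())) >= 50:
        sfs_neutral = popgen.build_sfs(neutral_counts, n, fold=True)
        dem_fit = dfe.fit_demography(sfs_neutral)
        demog = dfe.Demography(dem_fit.params["r"],
                               dem_fit.params["t2"])
        boot = dfe.bootstrap_dfe(sel_by_locus, sfs_neutral, n,
                                 B=counts["dfe_boot"],
                                 seed=stage_seed(config.seed, "dfe"),
                                 demography=demog)
        dfe_report = dict(
            demography=dict(r=demog.r, t2=demog.t2),
            edges=list(boot.edges),
            proportions=[float(x) for x in boot.proportions],
            boot_mean=[float(x) for x in boot.boot_mean],
            ci_lower=[float(x) for x in boot.ci_lower],
            ci_upper=[float(x) for x in boot.ci_upper],
            n_boot=boot.n_boot,
            n_selected=int(sum(map(len, sel_by_locus.values()))),
            n_neutral=len(neutral_counts))
        with open(os.path.join(config.outdir, "dfe_report.json"),
                  "w") as fh:
            json.dump(dfe_report, fh, indent=1, sort_keys=True)
        record("dfe", B=counts["dfe_boot"])
    else:
        record("dfe", skipped="not enough segregating sites")
    report["dfe"] = dfe_report

    # --- conservation -----------------------------------------------------
    cons_feats = [f for f in bundle.annotation.features
                  if f.feature_class in ("cds_exon", "lnc_exon",
                                         "lnc_intron", "pc_intron")]
    prof = conservation.metagene_profile(
        cons_feats, bundle.conservation,
        n_boot=counts["metagene_boot"],
        seed=stage_seed(config.seed, "conserve"))
    prof.table.to_csv(os.path.join(config.outdir,
                                   "metagene_profile.tsv"),
                      sep="\t", index=False)
    lnc_lengths = [len(f) for f in bundle.annotation.features
                   if f.feature_class == "lnc_exon"]
    band = conservation.control_profiles(
        bundle.annotation, bundle.chrom_lengths, bundle.conservation,
        lnc_lengths, n_sets=counts["control_sets"],
        seed=stage_seed(config.seed, "conserve-control"))
    pd.DataFrame(dict(decile=np.arange(1, 11), lower=band["lower"],
                      median=band["median"],
                      upper=band["upper"])).to_csv(
        os.path.join(config.outdir, "control_band.tsv"), sep="\t",
        index=False)
    ex_feats = [f for f in bundle.annotation.features
                if f.feature_class == "lnc_exon"]
    in_feats = [f for f in bundle.annotation.features
                if f.feature_class == "lnc_intron"]
    _em, _im, p_single = conservation.single_site_comparison(
        ex_feats, in_feats, bundle.conservation,
        n_resamples=counts["single_site_resamples"],
        seed=stage_seed(config.seed, "conserve-single"))
    report["conserve"] = dict(single_site_p=p_single,
                              n_profiled=sum(prof.n_features.values()))
    record("conserve", n_boot=counts["metagene_boot"])

    # splice-site information content: needs splice alignments, which the
    # fly-style cohort provides via its outgroup tracks; the human-like
    # preset carries none, so the sub-stage is skipped and logged
    if fly:
        rng_sp = np.random.default_rng(stage_seed(config.seed, "splice"))
        tracks = [bundle.reference] + bundle.outgroups
        blocks5 = []
        for lid, fs in bundle.annotation.gene_index.items():
            for f in fs:
                if f.feature_class != "lnc_intron":
                    continue
                p5 = f.start if f.strand == "+" else f.end - 2
                if p5 - 50 < 0 or p5 + 52 > bundle.chrom_lengths[f.chrom]:
                    continue
                blocks5.append([t[f.chrom][p5 - 50:p5 + 52]
                                .tobytes().decode() for t in tracks])
        if blocks5:
            prof5 = conservation.splice_site_information(blocks5, "5prime")
            inter = []
            for c, _L in bundle.chromosomes:
                ig = np.flatnonzero(bundle.annotation.class_codes(c)
                                    == CLASS_CODE["intergenic"])
                if len(ig):
                    brk = np.flatnonzero(np.diff(ig) > 1)
                    ss = np.concatenate(([0], brk + 1))
                    ee = np.concatenate((brk, [len(ig) - 1]))
                    inter.extend((c, int(ig[a]), int(ig[b]) + 1)
                                 for a, b in zip(ss, ee))
            ctrl_blocks = conservation.control_splice_blocks(
                tracks, inter, "GT", len(blocks5), rng_sp)
            ctrl = (conservation.splice_site_information(
                ctrl_blocks, "5prime") if ctrl_blocks else None)
            pd.DataFrame(dict(
                offset=prof5.columns, ic=prof5.information,
                control_ic=(ctrl.information if ctrl is not None
                            else np.nan))).to_csv(
                os.path.join(config.outdir, "splice_ic.tsv"), sep="\t",
                index=False)
            record("splice", n_blocks=prof5.n_blocks,
                   skipped_blocks=prof5.n_skipped)
    else:
        record("splice", skipped="no splice alignments in this preset")

    # --- synteny ----------------------------------------------------------
    annot_a, annot_b, orth, truth_pe = cohort.generate_species_pair(
        seed=stage_seed(config.seed, "synteny"))
    assign_a, _un_a = synteny.assign_all_anchors(annot_a)
    assign_b, _un_b = synteny.assign_all_anchors(annot_b)
    pe_pairs, control = synteny.classify_positional_equivalents(
        assign_a, assign_b, orth)
    pd.DataFrame(pe_pairs, columns=["lnc_a", "lnc_b"]).to_csv(
        os.path.join(config.outdir, "positional_equivalents.tsv"),
        sep="\t", index=False)
    pd.DataFrame(dict(lnc_a=control)).to_csv(
        os.path.join(config.outdir, "pe_controls.tsv"), sep="\t",
        index=False)
    report["synteny"] = dict(pe=len(pe_pairs), control=len(control))
    record("synteny", planted=len(truth_pe))

    # --- report -----------------------------------------------------------
    record("report")
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(os.path.join(config.outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
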