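"""Matched putatively-neutral reference sets.

Three constructions mirror the fly/human analysis designs: trimmed small
introns (<= 86 nt, first 6 and last 16 transcript-oriented bases removed)
from protein-coding genes directly neighbouring a lncRNA; ancestral repeats
in the intergenic blocks flanking a lncRNA; and N sites sampled uniformly
from conservation-masked flanking intergenic sequence, N matched to the
locus's analyzable exonic site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic import AnnotationSet, FeatureInterval


@dataclass(frozen=True)
class ProxySpec:
    kind: str = "small_intron"
    max_intron_len: int = 86
    trim5: int = 6
    trim3: int = 16
    max_distance: int = 5_000      # fly small introns; human ARs use 10 kb
    mask_identity: float = 0.90
    mask_window: int = 20
    mask_mode: str = "identity"    # identity | score
    score_threshold: float = 0.8   # used when mask_mode == "score"
    min_flank: int = 1_000
    seed: int = 0

    def __post_init__(self):
        if self.trim5 + self.trim3 >= self.max_intron_len:
            raise ValueError("trims leave no analyzable intron sequence")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")


def _gene_spans(annotation: AnnotationSet) -> dict[str, tuple]:
    """Spans of protein-coding loci (those with CDS exons)."""
    out = {}
    for lid, fs in annotation.gene_index.items():
        if any(f.feature_class == "cds_exon" for f in fs):
            out[lid] = annotation.locus_span(lid)
    return out


def _edge_distance(s1, e1, s2, e2) -> int:
    """Distance between closest edges of two intervals (0 if overlapping)."""
    if e1 <= s2:
        return s2 - e1
    if e2 <= s1:
        return s1 - e2
    return 0


def direct_neighbour_genes(annotation: AnnotationSet,
                           lnc_id: str) -> list[tuple[str, int]]:
    """Nearest protein-coding gene on each side of a lncRNA span, with edge
    distance; ties broken toward smaller distance then the 5' side."""
    chrom, s, e, strand = annotation.locus_span(lnc_id)
    left = right = None
    for gid, (gc, gs, ge, _gstr) in _gene_spans(annotation).items():
        if gc != chrom:
            continue
        if ge <= s:
            d = s - ge
            if left is None or d < left[1]:
                left = (gid, d)
        elif gs >= e:
            d = gs - e
            if right is None or d < right[1]:
                right = (gid, d)
    return [x for x in (left, right) if x is not None]


def select_small_introns(annotation: AnnotationSet,
                         spec: ProxySpec | None = None
                         ) -> list[FeatureInterval]:
    """Trimmed small introns of genes directly neighbouring a lncRNA.

    Keeps pc_introns of length <= max_intron_len in protein-coding genes
    that are the direct neighbour of some lncRNA locus within max_distance,
    trimmed to drop the first trim5 and last trim3 transcript-oriented
    bases.
    """
    spec = spec or ProxySpec()
    qualifying_genes: set[str] = set()
    for lnc in annotation.loci("lnc_exon"):
        for gid, d in direct_neighbour_genes(annotation, lnc):
            if d <= spec.max_distance:
                qualifying_genes.add(gid)
    out = []
    for gid in sorted(qualifying_genes):
        for f in annotation.gene_index[gid]:
            if f.feature_class != "pc_intron" or len(f) > spec.max_intron_len:
                continue
            if f.strand == "+":
                s, e = f.start + spec.trim5, f.end - spec.trim3
            else:
                s, e = f.start + spec.trim3, f.end - spec.trim5
            if e > s:
                out.append(FeatureInterval(f.chrom, s, e, f.strand,
                                           f.feature_class, f.locus_id,
                                           f.ordinal))
    return out


def select_flanking_ancestral_repeats(annotation: AnnotationSet,
                                      spec: ProxySpec | None = None):
    """Ancestral repeats within max_distance of a lncRNA span, lying in its
    flanking intergenic blocks; returns (repeats, retained lnc ids)."""
    spec = spec or ProxySpec(kind="ancestral_repeat", max_distance=10_000)
    ars = [f for f in annotation.features
           if f.feature_class == "ancestral_repeat"]
    kept: list[FeatureInterval] = []
    retained: set[str] = set()
    for lnc in annotation.loci("lnc_exon"):
        chrom, s, e, _ = annotation.locus_span(lnc)
        for ar in ars:
            if ar.chrom != chrom:
                continue
            if _edge_distance(ar.start, ar.end, s, e) <= spec.max_distance:
                kept.append(ar)
                retained.add(lnc)
    # dedupe while keeping order
    seen = set()
    uniq = []
    for ar in kept:
        key = (ar.chrom, ar.start, ar.end)
        if key not in seen:
            seen.add(key)
            uniq.append(ar)
    return uniq, sorted(retained)


def mask_conserved_elements(reference: np.ndarray, outgroup: np.ndarray,
                            intervals, spec: ProxySpec | None = None):
    """Mask conserved windows; return the unmasked sub-intervals.

    A position is masked when it lies inside a sliding window of
    mask_window bases whose reference/outgroup nucleotide identity is at
    least mask_identity. Masking is idempotent (windows are evaluated
    within each interval, and removing masked runs never creates new
    qualifying windows).
    """
    spec = spec or ProxySpec()
    w = spec.mask_window
    need = int(np.ceil(spec.mask_identity * w))
    out = []
    for (start, end) in intervals:
        if end - start < w:
            out.append((start, end))
            continue
        match = (reference[start:end] == outgroup[start:end]).astype(int)
        csum = np.concatenate(([0], np.cumsum(match)))
        wins = csum[w:] - csum[:-w]          # identity count per window
        masked = np.zeros(end - start, dtype=bool)
        hit = np.flatnonzero(wins >= need)
        for h in hit:
            masked[h:h + w] = True
        keep = ~masked
        # extract maximal unmasked runs
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        for rs, re in zip(run_starts, run_ends):
            out.append((start + int(idx[rs]), start + int(idx[re]) + 1))
    return out


def sample_matched_sites(n_sites: int, unmasked_intervals,
                         rng: np.random.Generator,
                         min_flank: int = 1_000) -> np.ndarray:
    """Sample exactly n_sites distinct positions uniformly from the masked
    flank; raises if the usable flank is too small for the locus."""
    pool = np.concatenate(
        [np.arange(s, e) for s, e in unmasked_intervals]
        or [np.empty(0, dtype=np.int64)])
    if len(pool) < min_flank:
        raise ValueError(
            f"usable flank of {len(pool)} nt is below the {min_flank} nt "
            "minimum")
    if n_sites > len(pool):
        raise ValueError(f"cannot sample {n_sites} sites from a flank of "
                         f"{len(pool)}")
    if n_sites == 0:
        return np.empty(0, dtype=np.int64)
    return np.sort(rng.choice(pool, size=n_sites, replace=False))


def mask_conserved_by_score(conservation: np.ndarray, intervals,
                            spec: ProxySpec | None = None):
    """Score-based alternative masker: drop positions whose conservation
    score reaches the threshold; suits settings where the outgroup is too
    close for window identity to separate conserved elements from the
    neutral background."""
    spec = spec or ProxySpec(mask_mode="score")
    out = []
    for (start, end) in intervals:
        seg = conservation[start:end]
        keep = ~(seg >= spec.score_threshold)
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        out.extend((start + int(idx[rs]), start + int(idx[re]) + 1)
                   for rs, re in zip(run_starts, run_ends))
    return out


@dataclass
class MatchedFlankSample:
    locus_id: str
    chrom: str
    n_sites: int
    positions: np.ndarray  # 0-based neutral-proxy positions


def flanking_intergenic_blocks(annotation: AnnotationSet,
                               chrom_lengths: dict[str, int],
                               lnc_id: str) -> list[tuple[int, int]]:
    """The two intergenic blocks adjacent to a lncRNA span (bounded by the
    nearest annotated feature on each side)."""
    chrom, s, e, _ = annotation.locus_span(lnc_id)
    left_bound, right_bound = 0, chrom_lengths[chrom]
    for f in annotation.features:
        if f.chrom != chrom or f.locus_id == lnc_id:
            continue
        if f.end <= s:
            left_bound = max(left_bound, f.end)
        elif f.start >= e:
            right_bound = min(right_bound, f.start)
    blocks = []
    if s > left_bound:
        blocks.append((left_bound, s))
    if right_bound > e:
        blocks.append((e, right_bound))
    return blocks


def matched_neutral_samples(bundle, spec: ProxySpec, seed: int = 0,
                            outgroup_index: int = 0):
    """Per-locus conservation-masked flank samples, N matched to the
    locus's exonic site count; returns (samples, exclusion log)."""
    rng = np.random.default_rng(seed)
    annotation = bundle.annotation
    lens = bundle.chrom_lengths
    samples: list[MatchedFlankSample] = []
    exclusions: list[tuple[str, str]] = []
    for lnc in annotation.loci("lnc_exon"):
        chrom, *_ = annotation.locus_span(lnc)
        n_sites = sum(len(f) for f in annotation.gene_index[lnc]
                      if f.feature_class == "lnc_exon")
        blocks = flanking_intergenic_blocks(annotation, lens, lnc)
        if spec.mask_mode == "score":
            unmasked = mask_conserved_by_score(
                bundle.conservation[chrom], blocks, spec)
        else:
            unmasked = mask_conserved_elements(
                bundle.reference[chrom],
                bundle.outgroups[outgroup_index][chrom], blocks, spec)
        try:
            pos = sample_matched_sites(n_sites, unmasked, rng,
                                       spec.min_flank)
        except ValueError as err:
            exclusions.append((lnc, str(err)))
            continue
        samples.append(MatchedFlankSample(lnc, chrom, n_sites, pos))
    return samples, exclusions
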