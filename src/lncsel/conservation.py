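"""Interspecific conservation profiling.

Metagene decile profiles of per-base conservation scores over exons and
introns (strand-oriented, median-of-medians, percentile-bootstrap CIs),
size-matched intergenic control envelopes, single-site resampling
comparisons, and splice-site information content (2 - Shannon entropy in
bits per alignment column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_WINDOWS = 10
N_BOOT = 10_000
N_CONTROL_SETS = 1_000
N_RESAMPLES = 1_000


@dataclass
class MetageneProfile:
    table: pd.DataFrame        # feature_class, ordinal, decile, median, lo, hi
    n_features: dict
    dropped: list


def _feature_scores(feature, conservation) -> np.ndarray:
    """Strand-oriented per-base scores of one feature."""
    arr = conservation[feature.chrom][feature.start:feature.end]
    return arr[::-1] if feature.strand == "-" else arr


def _decile_medians(scores: np.ndarray,
                    n_windows: int = N_WINDOWS) -> np.ndarray:
    """Median per decile; remainder bases go to the earlier windows."""
    parts = np.array_split(scores, n_windows)
    return np.array([np.nanmedian(p) for p in parts])


def metagene_profile(features, conservation, n_windows: int = N_WINDOWS,
                     n_boot: int = N_BOOT, seed: int = 0,
                     ci: float = 95.0) -> MetageneProfile:
    """Decile conservation profile per (feature_class, ordinal) group.

    Per decile the statistic is the median over features of per-portion
    median scores, with a percentile bootstrap (resampling features) for
    the CI. Features shorter than n_windows bases are dropped and logged.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple, list[np.ndarray]] = {}
    dropped = []
    for f in features:
        if len(f) < n_windows:
            dropped.append((f.locus_id, f.chrom, f.start, f.end,
                            "shorter_than_windows"))
            continue
        dec = _decile_medians(_feature_scores(f, conservation), n_windows)
        groups.setdefault((f.feature_class, f.ordinal), []).append(dec)
    if not groups:
        raise ValueError("no usable features for the metagene profile")
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    rows = []
    n_features = {}
    for (fclass, ordinal), decs in sorted(groups.items()):
        M = np.vstack(decs)              # features x deciles
        n_feat = M.shape[0]
        n_features[(fclass, ordinal)] = n_feat
        med = np.median(M, axis=0)
        idx = rng.integers(0, n_feat, size=(n_boot, n_feat))
        boots = np.median(M[idx, :], axis=1)   # n_boot x deciles
        lo = np.percentile(boots, lo_q, axis=0)
        hi = np.percentile(boots, hi_q, axis=0)
        for d in range(n_windows):
            rows.append(dict(feature_class=fclass, ordinal=ordinal,
                             decile=d + 1, median=med[d],
                             ci_lower=min(lo[d], med[d]),
                             ci_upper=max(hi[d], med[d])))
    return MetageneProfile(pd.DataFrame(rows), n_features, dropped)


def intergenic_space(annotation, chrom_lengths: dict[str, int],
                     min_gene_distance: int = 1_000):
    """Intervals lying more than min_gene_distance from any annotated
    locus (protein-coding or lncRNA), per chromosome."""
    allowed = {}
    for chrom, L in chrom_lengths.items():
        free = np.ones(L, dtype=bool)
        for f in annotation.features:
            if f.chrom != chrom or f.feature_class == "ancestral_repeat":
                continue
            s = max(0, f.start - min_gene_distance)
            e = min(L, f.end + min_gene_distance)
            free[s:e] = False
        allowed[chrom] = free
    return allowed


def control_profiles(annotation, chrom_lengths, conservation,
                     target_lengths, n_sets: int = N_CONTROL_SETS,
                     seed: int = 0, n_windows: int = N_WINDOWS,
                     min_gene_distance: int = 1_000):
    """Per-decile envelope (2.5/97.5 percentiles of set medians) over
    n_sets random intergenic interval sets matching the target feature
    size distribution; every control interval lies > min_gene_distance
    from any annotated gene."""
    rng = np.random.default_rng(seed)
    allowed = intergenic_space(annotation, chrom_lengths,
                               min_gene_distance)
    max_len = max(target_lengths)
    # candidate start positions per chromosome where a max-length interval
    # fits entirely in allowed space
    candidates = {}
    for chrom, free in allowed.items():
        ok = free.copy()
        csum = np.concatenate(([0], np.cumsum(free)))
        # start p is valid for length l iff csum[p+l]-csum[p] == l
        candidates[chrom] = (csum, np.flatnonzero(free))
    chroms = sorted(candidates)
    set_medians = np.empty((n_sets, n_windows))
    for s_i in range(n_sets):
        decs = []
        for ln in target_lengths:
            for _attempt in range(200):
                chrom = chroms[rng.integers(0, len(chroms))]
                csum, starts = candidates[chrom]
                if len(starts) == 0:
                    continue
                p = int(starts[rng.integers(0, len(starts))])
                if p + ln <= len(allowed[chrom]) and \
                        csum[p + ln] - csum[p] == ln:
                    decs.append(_decile_medians(
                        conservation[chrom][p:p + ln], n_windows))
                    break
            else:
                raise ValueError(
                    f"insufficient intergenic space for a {ln}-bp control "
                    f"interval (>{min_gene_distance} bp from genes)")
        set_medians[s_i] = np.median(np.vstack(decs), axis=0)
    return dict(lower=np.percentile(set_medians, 2.5, axis=0),
                upper=np.percentile(set_medians, 97.5, axis=0),
                median=np.median(set_medians, axis=0))


def single_site_comparison(exon_features, intron_features, conservation,
                           n_resamples: int = N_RESAMPLES, seed: int = 0):
    """Draw one site per feature per resample; returns the paired exon and
    intron medians and the one-sided empirical p (fraction of resamples
    with exon median <= intron median)."""
    rng = np.random.default_rng(seed)
    ex_scores = [np.asarray(_feature_scores(f, conservation))
                 for f in exon_features]
    in_scores = [np.asarray(_feature_scores(f, conservation))
                 for f in intron_features]
    if not ex_scores or not in_scores:
        raise ValueError("need at least one exon and one intron feature")
    ex_med = np.empty(n_resamples)
    in_med = np.empty(n_resamples)
    for r in range(n_resamples):
        ex_med[r] = np.median([s[rng.integers(0, len(s))]
                               for s in ex_scores])
        in_med[r] = np.median([s[rng.integers(0, len(s))]
                               for s in in_scores])
    p = float(np.mean(ex_med <= in_med))
    return ex_med, in_med, p


# ---------------------------------------------------------------------------
# splice-site information content

def column_information(bases) -> float | None:
    """IC = 2 - H (bits) of one alignment column; gaps/N excluded.

    Returns None when fewer than 3 ungapped bases remain.
    """
    clean = [b.upper() for b in bases if b.upper() in "ACGT"]
    if len(clean) < 3:
        return None
    _, counts = np.unique(clean, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log2(p)))
    return 2.0 - h


@dataclass
class SpliceSiteProfile:
    side: str
    columns: np.ndarray         # column offsets relative to the dinucleotide
    information: np.ndarray     # IC per reported column, NaN if dropped
    n_blocks: int
    n_skipped: int


def splice_site_information(blocks, side: str, flank: int = 50,
                            n_intronic: int = 20) -> SpliceSiteProfile:
    """Per-column information content at splice sites.

    Each block is a small alignment (list of equal-length sequences, one
    per species) of `flank` exonic bases, the splice dinucleotide, and
    `flank` intronic bases, oriented 5'->3' on the transcript. Reported
    columns are the dinucleotide plus the n_intronic adjacent intronic
    positions. Blocks whose dinucleotide columns have fewer than 3 ungapped
    bases are skipped and counted.
    """
    if side not in ("5prime", "3prime"):
        raise ValueError("side must be '5prime' or '3prime'")
    usable = []
    n_skipped = 0
    for blk in blocks:
        lens = {len(s) for s in blk}
        if len(lens) != 1:
            raise ValueError("block sequences must have equal length")
        L = lens.pop()
        if side == "5prime":
            dinuc = (flank, flank + 1)
        else:
            dinuc = (L - flank - 2, L - flank - 1)
        if any(column_information([s[c] for s in blk]) is None
               for c in dinuc):
            n_skipped += 1
            continue
        usable.append((blk, dinuc))
    if not usable:
        raise ValueError("no usable splice blocks")
    if side == "5prime":
        offsets = np.arange(0, 2 + n_intronic)       # GT then intron
    else:
        offsets = np.arange(-n_intronic, 2)          # intron then AG
    ic = np.full(len(offsets), np.nan)
    for j, off in enumerate(offsets):
        vals = []
        for blk, dinuc in usable:
            c = dinuc[0] + int(off)
            if 0 <= c < len(blk[0]):
                v = column_information([s[c] for s in blk])
                if v is not None:
                    vals.append(v)
        if vals:
            ic[j] = float(np.mean(vals))
    return SpliceSiteProfile(side, offsets, ic, len(usable), n_skipped)


def control_splice_blocks(tracks, intervals, dinucleotide: str,
                          n_blocks: int, rng: np.random.Generator,
                          flank: int = 50):
    """Pseudo-alignment blocks at random occurrences of a dinucleotide
    (GT or AG) inside the given intergenic intervals.

    `tracks` is a list of coordinate-aligned per-chromosome base tracks
    (reference first); each hit yields one block of len(tracks) sequences.
    """
    dn = np.frombuffer(dinucleotide.encode(), dtype="S1")
    hits = []
    for chrom, s, e in intervals:
        ref = tracks[0][chrom]
        seg = ref[s:e]
        pos = np.flatnonzero((seg[:-1] == dn[0]) & (seg[1:] == dn[1])) + s
        pos = pos[(pos >= flank) & (pos + 2 + flank <= len(ref))]
        hits.extend((chrom, int(p)) for p in pos)
    if not hits:
        return []
    idx = rng.choice(len(hits), size=min(n_blocks, len(hits)),
                     replace=False)
    blocks = []
    for i in idx:
        chrom, p = hits[i]
        blocks.append([t[chrom][p - flank:p + 2 + flank].tobytes().decode()
                       for t in tracks])
    return blocks
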