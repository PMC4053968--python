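"""Site-frequency spectra and classical polymorphism/divergence estimators.

Implements pairwise diversity (piT), Watterson's theta, Tajima's D with the
standard Tajima (1989) normalizing constants, SNP density, and Jukes-Cantor
corrected divergence k = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class SFS:
    """Site-frequency spectrum at fixed haplotype sample size n.

    Unfolded: counts[i-1] = number of sites with derived count i, i=1..n-1.
    Folded: counts[i-1] = sites with minor count i, i=1..floor(n/2).
    """
    n: int
    counts: np.ndarray
    folded: bool

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        want = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != want:
            raise ValueError(f"expected {want} bins, got {len(self.counts)}")
        if (self.counts < 0).any():
            raise ValueError("negative SFS bin")

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    def fold(self) -> "SFS":
        if self.folded:
            return SFS(self.n, self.counts.copy(), True)
        half = self.n // 2
        out = np.zeros(half, dtype=np.int64)
        for i in range(1, self.n):
            out[min(i, self.n - i) - 1] += self.counts[i - 1]
        return SFS(self.n, out, True)


@dataclass
class PopgenSummary:
    L: int
    S: int
    piT: float
    thetaW: float
    tajD: float  # NaN when S == 0
    snp_density: float


@dataclass
class DivergenceSummary:
    aligned_sites: int
    differences: int
    p: float
    k: float


def _derived_count(site) -> int:
    if hasattr(site, "derived_count"):
        return int(site.derived_count)
    return int(site)


def _sample_size(site, default):
    return int(getattr(site, "n_called", default))


def build_sfs(sites, n: int, fold: bool = False) -> SFS:
    """Bin sites (PolarisedSite objects or raw derived counts) into an SFS."""
    counts = np.zeros(n - 1, dtype=np.int64)
    for s in sites:
        if _sample_size(s, n) != n:
            raise ValueError(
                "mixed sample sizes: stratify sites by n before building an "
                "SFS")
        d = _derived_count(s)
        if not 0 < d < n:
            raise ValueError(f"derived count {d} not segregating at n={n}")
        counts[d - 1] += 1
    sfs = SFS(n, counts, False)
    return sfs.fold() if fold else sfs


def tajima_constants(n: int) -> dict[str, float]:
    """a1, a2, b1, b2, c1, c2, e1, e2 of Tajima's D for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def summarize_region(sites, L: int, n: int) -> PopgenSummary:
    """Per-site piT, thetaW and Tajima's D over L analyzed sites.

    piT uses the unbiased estimator 2*p*(1-p)*n/(n-1) per segregating site;
    Tajima's D is NaN when there are no segregating sites.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    S = len(sites)
    c = tajima_constants(n) if n > 1 else None
    if S == 0:
        return PopgenSummary(L, 0, 0.0, 0.0, float("nan"), 0.0)
    counts = np.array([_derived_count(s) for s in sites], dtype=float)
    for s in sites:
        if _sample_size(s, n) != n:
            raise ValueError("mixed sample sizes: stratify before summary")
    p = counts / n
    pi_total = float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1)))
    a1 = c["a1"]
    theta_w_total = S / a1
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    taj_d = ((pi_total - theta_w_total) / math.sqrt(var)
             if var > 0 else float("nan"))
    return PopgenSummary(L, S, pi_total / L, theta_w_total / L, taj_d, S / L)


def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction of a raw per-site difference."""
    if p < 0:
        raise ValueError("negative divergence")
    if p >= 0.75:
        raise ValueError(f"divergence p={p} at or beyond JC saturation 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


_VALID = frozenset(b"ACGT")


def jc_divergence(reference: np.ndarray, outgroup: np.ndarray,
                  positions) -> DivergenceSummary:
    """JC-corrected divergence over given 0-based positions of two tracks.

    Positions where either track is not a plain base (N, gap) are excluded
    from the aligned-site denominator.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) and (pos.min() < 0 or pos.max() >= min(len(reference),
                                                       len(outgroup))):
        raise IndexError("position outside track bounds")
    r = reference[pos]
    o = outgroup[pos]
    bases = [b"A", b"C", b"G", b"T"]
    ok = np.isin(r, bases) & np.isin(o, bases)
    aligned = int(ok.sum())
    if aligned == 0:
        return DivergenceSummary(0, 0, 0.0, 0.0)
    diffs = int(np.sum(r[ok] != o[ok]))
    p = diffs / aligned
    return DivergenceSummary(aligned, diffs, p, jc_correct(p))


def mean_sd(values):
    """Class-level aggregation: per-locus mean and SD, NaNs excluded."""
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(arr) == 0:
        return float("nan"), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
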