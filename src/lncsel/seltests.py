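"""Hypothesis tests for selection: generalized McDonald-Kreitman chi-square,
derived-allele-frequency spectrum comparisons, mutation-class splits, and
Bonferroni correction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

LOW_DAF_THRESHOLD = 0.01


@dataclass(frozen=True)
class MKTable:
    """2x2 polymorphism/divergence contrast: rows focal and neutral,
    columns polymorphic and divergent site counts."""
    focal_poly: int
    focal_div: int
    neutral_poly: int
    neutral_div: int

    def __post_init__(self):
        cells = (self.focal_poly, self.focal_div, self.neutral_poly,
                 self.neutral_div)
        if any(c < 0 for c in cells):
            raise ValueError("MK cells must be non-negative")
        if self.focal_poly + self.focal_div == 0 or \
           self.neutral_poly + self.neutral_div == 0:
            raise ValueError("each MK row needs at least one positive cell")


@dataclass
class SpectrumComparison:
    ks_statistic: float
    p_value: float
    prop_low_focal: float
    prop_low_neutral: float


def mk_test(table: MKTable, continuity: bool = False):
    """Pearson chi-square (1 df) on the MK 2x2 table.

    No continuity correction by default (intended for the large counts of
    genome-scale classes). Returns (chi2, df, p).
    """
    obs = np.array([[table.focal_poly, table.focal_div],
                    [table.neutral_poly, table.neutral_div]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("MK test undefined: a table margin is zero")
    expected = rows @ cols / total
    diff = np.abs(obs - expected)
    if continuity:
        diff = np.clip(diff - 0.5, 0.0, None)
    chi2 = float(np.sum(diff ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


def compare_daf_spectra(focal_dafs, neutral_dafs,
                        low_threshold: float = LOW_DAF_THRESHOLD
                        ) -> SpectrumComparison:
    """Two-sample KS comparison of DAF distributions plus the fraction of
    low-frequency (<= threshold) derived alleles in each sample."""
    focal = np.asarray(focal_dafs, dtype=float)
    neutral = np.asarray(neutral_dafs, dtype=float)
    if len(focal) == 0 or len(neutral) == 0:
        raise ValueError("both DAF samples must be non-empty")
    res = stats.ks_2samp(focal, neutral, method="asymp")
    return SpectrumComparison(
        float(res.statistic), float(res.pvalue),
        float(np.mean(focal <= low_threshold)),
        float(np.mean(neutral <= low_threshold)))


def mutation_class(ancestral: str, derived: str) -> str:
    """GC->AT / AT->GC / composition-neutral classification of one change."""
    a, d = ancestral.upper(), derived.upper()
    if a == d:
        raise ValueError("ancestral and derived alleles are identical")
    if a not in "ACGT" or d not in "ACGT":
        raise ValueError(f"invalid bases {ancestral}/{derived}")
    sw = {"G", "C"}
    if a in sw and d not in sw:
        return "GCtoAT"
    if a not in sw and d in sw:
        return "ATtoGC"
    return "neutral_class"


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values, min(1, p*m); m defaults to the family
    size (number of tests supplied)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, p * m)


def kruskal_wallis(*groups):
    """Tie-corrected Kruskal-Wallis H test across locus classes (df=k-1).

    Delegated to scipy; this wrapper fixes the contract used by the
    reporting layer.
    """
    clean = [np.asarray([v for v in g if np.isfinite(v)]) for g in groups]
    if any(len(g) == 0 for g in clean):
        raise ValueError("every group needs at least one finite value")
    res = stats.kruskal(*clean)
    return float(res.statistic), len(clean) - 1, float(res.pvalue)


def selection_efficacy_threshold(ne: float) -> float:
    """Minimum |s| for selection to overcome drift at effective size Ne.

    A mutation is effectively neutral when |Ne*s| is below ~1, so the
    threshold selection coefficient is 1/Ne.
    """
    if ne <= 0:
        raise ValueError("Ne must be positive")
    return 1.0 / ne
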