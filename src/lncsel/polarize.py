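"""SNP filtering and ancestral/derived polarization by outgroup parsimony.

Two filter profiles mirror the source datasets this pipeline emulates:
a fly-style profile (depth >= 10 reads, unambiguous calls in >= 150 of 162
strains) and a human-style profile (drop SNPs within 10 bp of an indel,
quality cutoff standing in for a 0.1% FDR threshold).

Polarization uses maximum parsimony against two outgroup tracks ordered
nearest-first; ambiguous configurations are removed, not guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .genomic import PopulationSite

AMBIGUOUS = "AMBIGUOUS"

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class FilterProfile:
    name: str
    min_coverage: int = 0
    min_called: int = 0
    exclude_near_indel: bool = False
    min_qual: float = 0.0


def filter_profile(name: str, **overrides) -> FilterProfile:
    """Named site-filter presets ('fly' or 'human')."""
    presets = {
        "fly": dict(min_coverage=10, min_called=150),
        "human": dict(exclude_near_indel=True, min_qual=30.0),
    }
    if name not in presets:
        raise ValueError(f"unknown filter profile {name!r}")
    kw = presets[name] | overrides
    return FilterProfile(name=name, **kw)


def filter_sites(sites: Iterable[PopulationSite],
                 profile: FilterProfile):
    """Apply a profile; returns (kept sites, rejection tally by reason).

    A site failing several thresholds is tallied under the first failing
    reason, in the order coverage, called-sample count, indel proximity,
    quality; the tally plus kept count always sums to the input size.
    """
    kept = []
    tally: dict[str, int] = {}

    def rej(reason):
        tally[reason] = tally.get(reason, 0) + 1

    for s in sites:
        if s.coverage < profile.min_coverage:
            rej("low_coverage")
        elif s.n_called < profile.min_called:
            rej("low_call_count")
        elif profile.exclude_near_indel and s.near_indel:
            rej("near_indel")
        elif s.qual < profile.min_qual:
            rej("low_qual")
        else:
            kept.append(s)
    return kept, tally


@dataclass
class PolarisedSite(PopulationSite):
    ancestral_allele: str = ""
    derived_allele: str = ""
    derived_count: int = 0

    @property
    def daf(self) -> float:
        return self.derived_count / self.n_called


def polarize_site(alleles: tuple[str, str],
                  outgroup_bases: tuple[str, ...],
                  policy: str = "strict") -> str:
    """Parsimony ancestral allele of one biallelic site, or AMBIGUOUS.

    strict: both outgroups must carry the same base and that base must be
    one of the two segregating alleles. nearest: the nearest outgroup wins
    when it carries a segregating allele, unless the farther outgroup
    carries the *other* segregating allele (a contradiction); an unusable
    nearest outgroup falls back to the farther one.
    """
    a1, a2 = alleles
    if a1 == a2:
        raise ValueError("site is not biallelic (identical alleles)")
    if a1 not in _VALID_BASES or a2 not in _VALID_BASES:
        raise ValueError(f"invalid alleles {alleles}")
    obs = [b if b in _VALID_BASES else None for b in outgroup_bases]
    if policy == "strict":
        if len(obs) < 2 or obs[0] is None or obs[1] is None:
            return AMBIGUOUS
        if obs[0] != obs[1] or obs[0] not in (a1, a2):
            return AMBIGUOUS
        return obs[0]
    if policy == "nearest":
        near = obs[0] if obs else None
        far = obs[1] if len(obs) > 1 else None
        if near in (a1, a2):
            other = a2 if near == a1 else a1
            return AMBIGUOUS if far == other else near
        if far in (a1, a2):
            return far
        return AMBIGUOUS
    raise ValueError(f"unknown polarization policy {policy!r}")


def polarize_all(sites: Iterable[PopulationSite],
                 outgroup_tracks: list[dict],
                 policy: str = "strict"):
    """Polarize every site against per-chromosome outgroup base tracks.

    Sites whose outgroup configuration is ambiguous (including missing
    outgroup coverage) are dropped and counted, matching the removal of
    ambiguous sites from the final dataset.
    """
    polarised: list[PolarisedSite] = []
    n_ambiguous = 0
    for s in sites:
        bases = []
        for track in outgroup_tracks:
            arr = track.get(s.chrom)
            if arr is None or not (0 <= s.pos - 1 < len(arr)):
                bases.append("N")
            else:
                bases.append(arr[s.pos - 1].decode())
        anc = polarize_site((s.ref_allele, s.alt_allele), tuple(bases),
                            policy=policy)
        if anc == AMBIGUOUS:
            n_ambiguous += 1
            continue
        der = s.alt_allele if anc == s.ref_allele else s.ref_allele
        dcount = (s.allele_count if der == s.alt_allele
                  else s.n_called - s.allele_count)
        polarised.append(PolarisedSite(
            s.chrom, s.pos, s.ref_allele, s.alt_allele, s.allele_count,
            s.n_called, s.coverage, s.qual, s.near_indel,
            ancestral_allele=anc, derived_allele=der, derived_count=dcount))
    return polarised, n_ambiguous
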