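"""Shared genomic data model: sequence tracks, annotation intervals, variants.

Coordinates are half-open 0-based everywhere in memory; 1-based conventions
appear only at the VCF text boundary. Feature classes follow a fixed
precedence so that every reference position belongs to exactly one class.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Precedence order: earlier wins when intervals overlap.
FEATURE_CLASSES = (
    "cds_exon",
    "utr5",
    "utr3",
    "pc_intron",
    "lnc_exon",
    "lnc_intron",
    "ancestral_repeat",
    "intergenic",
)
CLASS_CODE = {c: i for i, c in enumerate(FEATURE_CLASSES)}
ORDINALS = ("first", "middle", "last", "unique")

_BASES = ("A", "C", "G", "T")

NEAR_INDEL_BP = 10  # SNPs within this many bp of an indel call are flagged


class ParseError(ValueError):
    """Malformed record in an input file."""


class BoundsError(ValueError):
    """Interval or position outside chromosome bounds."""


@dataclass(frozen=True)
class FeatureInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    feature_class: str
    locus_id: str | None = None
    ordinal: str = "unique"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise BoundsError(
                f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.feature_class not in CLASS_CODE:
            raise ParseError(f"unknown feature class {self.feature_class!r}")
        if self.ordinal not in ORDINALS:
            raise ParseError(f"unknown ordinal {self.ordinal!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PopulationSite:
    """One biallelic SNP with the sample-level metadata the filters need."""
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    allele_count: int
    n_called: int
    coverage: int = 0
    qual: float = 0.0
    near_indel: bool = False


@dataclass
class IndelRecord:
    chrom: str
    pos: int  # 1-based position of the VCF record
    ref: str
    alt: str


class AnnotationSet:
    """Feature intervals plus locus-level indexes used downstream."""

    def __init__(self, features, ortholog_map=None):
        self.features: list[FeatureInterval] = sorted(
            features, key=lambda f: (f.chrom, f.start, f.end, f.feature_class))
        self.ortholog_map: dict[str, str] = dict(ortholog_map or {})
        self.gene_index: dict[str, list[FeatureInterval]] = {}
        for f in self.features:
            if f.locus_id:
                self.gene_index.setdefault(f.locus_id, []).append(f)
        # transcript order within each locus
        for lid, fs in self.gene_index.items():
            rev = fs[0].strand == "-"
            fs.sort(key=lambda f: f.start, reverse=rev)
        self._pos_index: dict[str, np.ndarray] | None = None

    def loci(self, *classes: str) -> list[str]:
        """Locus ids having at least one feature in any of `classes`."""
        out = []
        for lid, fs in self.gene_index.items():
            if any(f.feature_class in classes for f in fs):
                out.append(lid)
        return sorted(out)

    def locus_span(self, locus_id: str) -> tuple[str, int, int, str]:
        fs = self.gene_index[locus_id]
        return (fs[0].chrom, min(f.start for f in fs),
                max(f.end for f in fs), fs[0].strand)

    def build_index(self, chrom_lengths: dict[str, int]) -> None:
        """Precedence-resolved per-base feature index (int32 into features)."""
        idx = {c: np.full(n, -1, dtype=np.int32)
               for c, n in chrom_lengths.items()}
        order = sorted(range(len(self.features)),
                       key=lambda i: CLASS_CODE[self.features[i].feature_class],
                       reverse=True)  # paint low precedence first
        for i in order:
            f = self.features[i]
            if f.chrom not in idx:
                raise BoundsError(f"feature on unknown chromosome {f.chrom}")
            if f.end > len(idx[f.chrom]):
                raise BoundsError(
                    f"{f.chrom}:{f.start}-{f.end} beyond chromosome end")
            idx[f.chrom][f.start:f.end] = i
        self._pos_index = idx

    def site_class(self, chrom: str, pos: int) -> tuple[str, str | None, str]:
        """(feature_class, locus_id, ordinal) of a 0-based position."""
        if self._pos_index is None:
            raise RuntimeError("call build_index() first")
        arr = self._pos_index[chrom]
        if pos < 0 or pos >= len(arr):
            raise BoundsError(f"{chrom}:{pos} off chromosome")
        i = int(arr[pos])
        if i < 0:
            return ("intergenic", None, "unique")
        f = self.features[i]
        return (f.feature_class, f.locus_id, f.ordinal)

    def class_codes(self, chrom: str) -> np.ndarray:
        """Per-base feature-class codes (CLASS_CODE) for one chromosome."""
        if self._pos_index is None:
            raise RuntimeError("call build_index() first")
        arr = self._pos_index[chrom]
        codes = np.full(len(arr), CLASS_CODE["intergenic"], dtype=np.int8)
        hit = arr >= 0
        if hit.any():
            fc = np.fromiter(
                (CLASS_CODE[self.features[i].feature_class]
                 for i in arr[hit]), dtype=np.int8, count=int(hit.sum()))
            codes[hit] = fc
        return codes

    def validate(self, chrom_lengths: dict[str, int] | None = None) -> None:
        if chrom_lengths:
            for f in self.features:
                if f.chrom not in chrom_lengths:
                    raise BoundsError(f"unknown chromosome {f.chrom}")
                if f.end > chrom_lengths[f.chrom]:
                    raise BoundsError(
                        f"{f.chrom}:{f.start}-{f.end} beyond chromosome end")
        # lncRNA loci are intergenic by construction
        pc = [f for f in self.features
              if f.feature_class in ("cds_exon", "utr5", "utr3", "pc_intron")]
        spans: dict[str, tuple] = {}
        for f in pc:
            c, s, e = f.chrom, f.start, f.end
            if f.locus_id not in spans:
                spans[f.locus_id] = (c, s, e)
            else:
                _, s0, e0 = spans[f.locus_id]
                spans[f.locus_id] = (c, min(s, s0), max(e, e0))
        for f in self.features:
            if not f.feature_class.startswith("lnc_"):
                continue
            for (c, s, e) in spans.values():
                if f.chrom == c and f.start < e and f.end > s:
                    raise ParseError(
                        f"lncRNA feature {f.locus_id} overlaps a "
                        "protein-coding gene span")
        # introns exactly fill inter-exon gaps
        for lid, fs in self.gene_index.items():
            exons = [f for f in fs if f.feature_class in ("cds_exon",
                                                          "lnc_exon")]
            introns = [f for f in fs if f.feature_class in ("pc_intron",
                                                            "lnc_intron")]
            if len(exons) < 2 or not introns:
                continue
            exons_g = sorted(exons, key=lambda f: f.start)
            gaps = {(a.end, b.start)
                    for a, b in zip(exons_g[:-1], exons_g[1:])
                    if b.start > a.end}
            got = {(i.start, i.end) for i in introns}
            if not gaps <= got:
                raise ParseError(f"locus {lid}: introns do not fill gaps")


@dataclass
class GenomeBundle:
    """Everything one analysis run consumes, in memory."""
    chromosomes: list[tuple[str, int]]
    reference: dict[str, np.ndarray]          # dtype S1 per chromosome
    outgroups: list[dict[str, np.ndarray]]    # nearest-first
    conservation: dict[str, np.ndarray]       # float in [0,1], NaN = missing
    variants: list[PopulationSite]
    annotation: AnnotationSet
    indels: list[IndelRecord] = field(default_factory=list)
    sample_size: int = 0  # haplotypes genotyped (max AN seen)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lens = self.chrom_lengths
        for name, n in self.chromosomes:
            if len(self.reference.get(name, ())) != n:
                raise ParseError(f"reference track length mismatch on {name}")
            for og in self.outgroups:
                if len(og.get(name, ())) != n:
                    raise ParseError(f"outgroup track length mismatch on "
                                     f"{name}")
            if self.conservation and len(self.conservation.get(name,
                                                               ())) != n:
                raise ParseError(f"conservation track length mismatch on "
                                 f"{name}")
        self.annotation.validate(lens)
        for v in self.variants:
            if not (0 < v.allele_count < v.n_called):
                raise ParseError(
                    f"{v.chrom}:{v.pos} not segregating after filtering")


# ---------------------------------------------------------------------------
# codon degeneracy

def _aa(codon: str) -> str:
    tbl = standard_dna_table
    if codon in tbl.stop_codons:
        return "*"
    return tbl.forward_table[codon]


def classify_degeneracy(codon: str, codon_pos: int) -> int | None:
    """Degeneracy class (0/2/3/4-fold) of one codon position.

    Counts the alternative bases at ``codon_pos`` (1-based within the codon)
    that leave the encoded amino acid unchanged: 0 alternatives -> 0-fold,
    1 -> 2-fold, 2 -> 3-fold, 3 -> 4-fold. Ambiguous bases give ``None``.
    """
    codon = codon.upper()
    if len(codon) != 3 or codon_pos not in (1, 2, 3):
        raise ValueError("need a 3-base codon and codon_pos in {1,2,3}")
    if any(b not in _BASES for b in codon):
        return None
    aa = _aa(codon)
    i = codon_pos - 1
    n_syn = 0
    for b in _BASES:
        if b == codon[i]:
            continue
        alt = codon[:i] + b + codon[i + 1:]
        if _aa(alt) == aa:
            n_syn += 1
    return {0: 0, 1: 2, 2: 3, 3: 4}[n_syn]


def build_degeneracy_table(bundle: GenomeBundle) -> dict[str, np.ndarray]:
    """Per-base degeneracy codes: -1 outside CDS / NA, else 0,2,3,4.

    CDS exons of each locus are concatenated in transcript orientation and
    translated in frame from the annotated start.
    """
    out = {name: np.full(n, -1, dtype=np.int8)
           for name, n in bundle.chromosomes}
    for lid, fs in bundle.annotation.gene_index.items():
        cds = [f for f in fs if f.feature_class == "cds_exon"]
        if not cds:
            continue
        strand = cds[0].strand
        chrom = cds[0].chrom
        ref = bundle.reference[chrom]
        # genomic positions in transcript order
        pos_lists = []
        for f in cds:  # gene_index is already transcript-ordered
            p = np.arange(f.start, f.end)
            if strand == "-":
                p = p[::-1]
            pos_lists.append(p)
        pos = np.concatenate(pos_lists)
        seq = ref[pos].tobytes().decode()
        if strand == "-":
            seq = str(Seq(seq).complement())
        usable = len(seq) - len(seq) % 3
        for i in range(0, usable, 3):
            codon = seq[i:i + 3]
            for j in range(3):
                d = classify_degeneracy(codon, j + 1)
                out[chrom][pos[i + j]] = -1 if d is None else d
    return out


# ---------------------------------------------------------------------------
# readers / writers

def _read_fasta_tracks(path: str) -> dict[str, np.ndarray]:
    tracks = {}
    for rec in SeqIO.parse(path, "fasta"):
        tracks[rec.id] = np.frombuffer(
            str(rec.seq).upper().encode(), dtype="S1").copy()
    return tracks


def _write_fasta_tracks(tracks: dict[str, np.ndarray], path: str) -> None:
    recs = [SeqRecord(Seq(arr.tobytes().decode()), id=name, description="")
            for name, arr in tracks.items()]
    SeqIO.write(recs, path, "fasta")


def read_annotation_bed(path: str) -> list[FeatureInterval]:
    """BED6 with name = locus_id|feature_class|ordinal."""
    feats = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{ln}: expected 6 BED columns")
            chrom, start, end, name, _score, strand = parts[:6]
            bits = name.split("|")
            if len(bits) != 3:
                raise ParseError(
                    f"{path}:{ln}: name must be locus|class|ordinal")
            locus, fclass, ordinal = bits
            try:
                feats.append(FeatureInterval(
                    chrom, int(start), int(end), strand, fclass,
                    locus or None, ordinal))
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
    return feats


def write_annotation_bed(features, path: str) -> None:
    with open(path, "w") as fh:
        for f in sorted(features, key=lambda f: (f.chrom, f.start, f.end,
                                                 f.feature_class)):
            name = f"{f.locus_id or ''}|{f.feature_class}|{f.ordinal}"
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t"
                     f"{f.strand}\n")


def read_conservation_bedgraph(path: str,
                               chrom_lengths: dict[str, int]
                               ) -> dict[str, np.ndarray]:
    cons = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            try:
                chrom, s, e, v = line.split("\t")
                s, e, v = int(s), int(e), float(v)
            except ValueError as err:
                raise ParseError(f"{path}:{ln}: bad bedGraph line") from err
            if chrom not in cons or e > chrom_lengths[chrom]:
                raise BoundsError(f"{path}:{ln}: interval off chromosome")
            cons[chrom][s:e] = v
    return cons


def write_conservation_bedgraph(cons: dict[str, np.ndarray],
                                path: str, decimals: int = 4) -> None:
    """Run-length-compressed bedGraph (values rounded for compactness)."""
    with open(path, "w") as fh:
        for chrom in sorted(cons):
            vals = np.round(cons[chrom], decimals)
            if len(vals) == 0:
                continue
            breaks = np.flatnonzero(
                ~np.isclose(vals[1:], vals[:-1], equal_nan=True)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Called haplotypes">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Min per-strain depth proxy">
##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">
"""


def write_vcf(sites, indels, path: str,
              chromosomes: list[tuple[str, int]],
              ancestral: dict[tuple[str, int], str] | None = None) -> None:
    """Plain-text VCF with SNP and indel records interleaved by position."""
    ancestral = ancestral or {}
    recs = []
    for v in sites:
        info = f"AC={v.allele_count};AN={v.n_called};DP={v.coverage}"
        aa = ancestral.get((v.chrom, v.pos))
        if aa:
            info += f";AA={aa}"
        recs.append((v.chrom, v.pos,
                     f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t{v.qual:.1f}\tPASS\t{info}"))
    for d in indels:
        recs.append((d.chrom, d.pos,
                     f"{d.chrom}\t{d.pos}\t.\t{d.ref}\t{d.alt}\t50.0\t"
                     f"PASS\t."))
    recs.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, n in chromosomes:
            fh.write(f"##contig=<ID={name},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, _, line in recs:
            fh.write(line + "\n")


def read_vcf(path: str):
    """Parse a VCF into (SNP sites, indel records, rejected count, max AN).

    Multiallelic records are rejected (counted, not kept); indels are kept
    separately so callers can set near-indel flags.
    """
    from cyvcf2 import VCF
    sites, indels, rejected = [], [], 0
    max_an = 0
    for rec in VCF(path):
        alts = rec.ALT
        if len(alts) != 1:
            rejected += 1
            continue
        ref, alt = rec.REF, alts[0]
        if len(ref) != 1 or len(alt) != 1:
            indels.append(IndelRecord(rec.CHROM, rec.POS, ref, alt))
            continue
        ac = rec.INFO.get("AC")
        an = rec.INFO.get("AN")
        dp = rec.INFO.get("DP") or 0
        if ac is None or an is None:
            rejected += 1
            continue
        max_an = max(max_an, int(an))
        sites.append(PopulationSite(
            rec.CHROM, rec.POS, ref, alt, int(ac), int(an),
            coverage=int(dp), qual=float(rec.QUAL or 0.0)))
    return sites, indels, rejected, max_an


def flag_near_indels(sites, indels, window: int = NEAR_INDEL_BP) -> None:
    """Set near_indel on SNPs within `window` bp of any indel call."""
    by_chrom: dict[str, list[int]] = {}
    for d in indels:
        by_chrom.setdefault(d.chrom, []).append(d.pos)
    for c in by_chrom:
        by_chrom[c] = np.array(sorted(by_chrom[c]))
    for v in sites:
        arr = by_chrom.get(v.chrom)
        if arr is None or len(arr) == 0:
            continue
        i = np.searchsorted(arr, v.pos)
        near = False
        if i < len(arr) and arr[i] - v.pos <= window:
            near = True
        if i > 0 and v.pos - arr[i - 1] <= window:
            near = True
        v.near_indel = near


def read_ortholog_tsv(path: str) -> dict[str, str]:
    """Strict 1-to-1 ortholog map (speciesA_id -> speciesB_id)."""
    amap: dict[str, str] = {}
    seen_b: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected 2 columns")
            a, b = parts
            if a in amap or b in seen_b:
                raise ParseError(
                    f"{path}:{ln}: ortholog map not 1-to-1 at {a}/{b}")
            amap[a] = b
            seen_b.add(b)
    return amap


def load_bundle(paths: dict, config: dict | None = None) -> GenomeBundle:
    """Assemble and validate a GenomeBundle from on-disk files.

    `paths` keys: reference, outgroups (list), vcf, annotation,
    conservation (optional), orthologs (optional).
    """
    config = config or {}
    for key in ("reference", "vcf", "annotation"):
        if key not in paths:
            raise ValueError(f"missing required path {key!r}")
    reference = _read_fasta_tracks(paths["reference"])
    chromosomes = [(c, len(a)) for c, a in sorted(reference.items())]
    lens = dict(chromosomes)
    outgroups = [_read_fasta_tracks(p) for p in paths.get("outgroups", [])]
    feats = read_annotation_bed(paths["annotation"])
    orth = (read_ortholog_tsv(paths["orthologs"])
            if paths.get("orthologs") else None)
    annotation = AnnotationSet(feats, orth)
    annotation.build_index(lens)
    cons = (read_conservation_bedgraph(paths["conservation"], lens)
            if paths.get("conservation") else {})
    sites, indels, rejected, max_an = read_vcf(paths["vcf"])
    flag_near_indels(sites, indels)
    bundle = GenomeBundle(chromosomes, reference, outgroups, cons,
                          sites, annotation, indels, sample_size=max_an)
    bundle.n_rejected_multiallelic = rejected
    bundle.validate()
    return bundle


def write_bundle(bundle: GenomeBundle, outdir: str,
                 ancestral: dict | None = None) -> dict:
    """Write the full file set; returns the path map load_bundle accepts."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "reference": os.path.join(outdir, "reference.fa"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "annotation": os.path.join(outdir, "annotation.bed"),
        "outgroups": [os.path.join(outdir, f"outgroup{i + 1}.fa")
                      for i in range(len(bundle.outgroups))],
    }
    _write_fasta_tracks(bundle.reference, paths["reference"])
    for og, p in zip(bundle.outgroups, paths["outgroups"]):
        _write_fasta_tracks(og, p)
    write_annotation_bed(bundle.annotation.features, paths["annotation"])
    write_vcf(bundle.variants, bundle.indels, paths["vcf"],
              bundle.chromosomes, ancestral)
    if bundle.conservation:
        paths["conservation"] = os.path.join(outdir, "conservation.bedgraph")
        write_conservation_bedgraph(bundle.conservation,
                                    paths["conservation"])
    if bundle.annotation.ortholog_map:
        paths["orthologs"] = os.path.join(outdir, "orthologs.tsv")
        with open(paths["orthologs"], "w") as fh:
            for a, b in sorted(bundle.annotation.ortholog_map.items()):
                fh.write(f"{a}\t{b}\n")
    return paths
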