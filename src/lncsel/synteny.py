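"""Positional equivalence of lncRNAs between two species.

A lncRNA is anchored to its nearest flanking protein-coding gene; two
lncRNAs in different species are positional equivalents when their anchors
are 1-to-1 orthologs and the lncRNAs sit on the same side of the anchor
with the same relative transcriptional orientation. LncRNAs whose anchors
are orthologous but whose side or orientation mismatches form the control
set.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic import AnnotationSet
from .proxies import direct_neighbour_genes


@dataclass(frozen=True)
class SyntenyAssignment:
    lnc_id: str
    anchor_id: str
    side: str          # 5prime_of_gene | 3prime_of_gene
    orientation: str   # same | opposite
    distance: int      # bp between closest edges


def assign_anchor(lnc_id: str,
                  annotation: AnnotationSet) -> SyntenyAssignment | None:
    """Anchor a lncRNA to its nearest flanking protein-coding gene.

    Ties (equidistant genes on both sides) are broken toward the gene on
    the lncRNA's 5' side. Returns None when no flanking gene exists.
    """
    neighbours = direct_neighbour_genes(annotation, lnc_id)
    if not neighbours:
        return None
    chrom, s, e, lnc_strand = annotation.locus_span(lnc_id)
    scored = []
    for gid, dist in neighbours:
        gc, gs, ge, g_strand = annotation.locus_span(gid)
        left_of_lnc = ge <= s
        # 5' side of the *lncRNA* for the tie-break
        on_lnc_5prime = left_of_lnc == (lnc_strand == "+")
        # side of the anchor the lncRNA occupies, in the gene's orientation
        lnc_left_of_gene = e <= gs
        if g_strand == "+":
            side = ("5prime_of_gene" if lnc_left_of_gene
                    else "3prime_of_gene")
        else:
            side = ("3prime_of_gene" if lnc_left_of_gene
                    else "5prime_of_gene")
        orientation = "same" if g_strand == lnc_strand else "opposite"
        scored.append((dist, 0 if on_lnc_5prime else 1,
                       SyntenyAssignment(lnc_id, gid, side, orientation,
                                         dist)))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]


def assign_all_anchors(annotation: AnnotationSet):
    """Anchor every lncRNA locus; returns (assignments, unanchored ids)."""
    out = {}
    unanchored = []
    for lnc in annotation.loci("lnc_exon"):
        a = assign_anchor(lnc, annotation)
        if a is None:
            unanchored.append(lnc)
        else:
            out[lnc] = a
    return out, unanchored


def classify_positional_equivalents(assignments_a: dict,
                                    assignments_b: dict,
                                    ortholog_map: dict[str, str]):
    """Split species-A lncRNAs into PE pairs and the mismatch control set.

    PE pair: both species' lncRNAs anchor to orthologous genes with the
    same side and the same relative orientation. Control: the anchors are
    orthologous and both flank a lncRNA, but side or orientation differ.
    lncRNAs whose anchor has no 1-to-1 ortholog (or no anchored lncRNA in
    the other species) are neither.
    """
    vals = list(ortholog_map.values())
    if len(set(ortholog_map)) != len(ortholog_map) or \
            len(set(vals)) != len(vals):
        raise ValueError("ortholog map must be strictly 1-to-1")
    by_anchor_b: dict[str, list] = {}
    for lnc_b, ab in assignments_b.items():
        by_anchor_b.setdefault(ab.anchor_id, []).append(ab)
    pe_pairs = []
    control = []
    for lnc_a, aa in sorted(assignments_a.items()):
        ortho = ortholog_map.get(aa.anchor_id)
        if ortho is None:
            continue
        partners = by_anchor_b.get(ortho, [])
        if not partners:
            continue
        matched = [ab for ab in partners
                   if ab.side == aa.side and
                   ab.orientation == aa.orientation]
        if matched:
            pe_pairs.append((lnc_a, matched[0].lnc_id))
        else:
            control.append(lnc_a)
    return pe_pairs, control
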