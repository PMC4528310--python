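"""Variant consequence classification against single-transcript gene models.

Categories: missense, nonsense, synonymous, frameshift_indel, inframe_indel,
splice_site, noncoding.  Splice sites are the two intronic bases on either
side of each internal exon boundary (the canonical donor/acceptor
dinucleotides); exonic junction bases are classified by their coding effect.
Indels that span a CDS/intron boundary are classified splice_site.
Stop-loss and start-loss substitutions are binned as missense.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from consomatic.util import percent
from consomatic.variants import GeneModel, ReferenceGenome, Variant, _revcomp

PROTEIN_ALTERING = ("missense", "nonsense", "frameshift_indel", "inframe_indel", "splice_site")
CATEGORIES = PROTEIN_ALTERING + ("synonymous", "noncoding")

SPLICE_FLANK = 2  # intronic bases on each side of an exon counted as splice site


@dataclass(frozen=True)
class ConsequenceCall:
    variant: Variant
    gene_id: str | None
    consequence: str

    @property
    def protein_altering(self) -> bool:
        return self.consequence in PROTEIN_ALTERING


def _covered_positions(v: Variant) -> range:
    # an insertion's edit sits between its anchor base and the next one
    return range(v.pos, v.end + 1)


def classify(variant: Variant, gene: GeneModel, ref_genome: ReferenceGenome) -> ConsequenceCall:
    """Classify a normalized variant against one gene model.

    Raises :class:`consomatic.variants.CoordinateError` via the reference
    lookup if the variant lies outside its contig.
    """
    ref_genome.slice(variant.chrom, variant.pos, variant.end)  # coordinate check
    if variant.chrom != gene.chrom:
        return ConsequenceCall(variant, None, "noncoding")

    splice = gene.splice_positions(SPLICE_FLANK)
    covered = set(_covered_positions(variant))
    if covered & splice:
        return ConsequenceCall(variant, gene.gene_id, "splice_site")

    cds_intervals = gene.cds_intervals()
    in_cds = lambda p: any(s <= p <= e for s, e in cds_intervals)  # noqa: E731

    if variant.vclass == "snv":
        if not in_cds(variant.pos):
            return ConsequenceCall(variant, None, "noncoding")
        return ConsequenceCall(variant, gene.gene_id, _snv_coding_effect(variant, gene, ref_genome))

    # Indel: coding if any deleted base, or the insertion anchor, is in CDS.
    if len(variant.ref) > 1:  # deletion (or complex): bases after the anchor are removed
        touched = [p for p in range(variant.pos + 1, variant.end + 1)]
    else:  # pure insertion: anchored at pos
        touched = [variant.pos]
    if not any(in_cds(p) for p in touched):
        return ConsequenceCall(variant, None, "noncoding")
    if not all(in_cds(p) for p in touched):
        # partially coding: treat boundary-overlapping indels as splice-disrupting
        return ConsequenceCall(variant, gene.gene_id, "splice_site")
    delta = abs(len(variant.ref) - len(variant.alt))
    kind = "frameshift_indel" if delta % 3 else "inframe_indel"
    return ConsequenceCall(variant, gene.gene_id, kind)


def _snv_coding_effect(variant: Variant, gene: GeneModel, ref_genome: ReferenceGenome) -> str:
    cds_pos = gene.cds_positions()  # genomic order
    i = cds_pos.index(variant.pos)
    if gene.strand == "-":
        i = len(cds_pos) - 1 - i
    cds_seq = gene.cds_sequence(ref_genome)
    codon_idx = i // 3
    codon = list(cds_seq[3 * codon_idx : 3 * codon_idx + 3])
    alt_base = variant.alt if gene.strand == "+" else _revcomp(variant.alt)
    offset = i % 3
    assert codon[offset] == (variant.ref if gene.strand == "+" else _revcomp(variant.ref))
    ref_aa = str(Seq("".join(codon)).translate())
    codon[offset] = alt_base
    alt_aa = str(Seq("".join(codon)).translate())
    if alt_aa == ref_aa:
        return "synonymous"
    if alt_aa == "*":
        return "nonsense"
    return "missense"  # includes stop-loss and start-loss


def annotate(
    variants: Iterable[Variant],
    genes: Sequence[GeneModel],
    ref_genome: ReferenceGenome,
) -> list[ConsequenceCall]:
    """Classify each variant against the gene whose span contains it.

    Genes are single-transcript and non-overlapping in this pipeline; a
    variant hitting no gene footprint (exons plus splice flanks) is
    noncoding.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for v in variants:
        call = ConsequenceCall(v, None, "noncoding")
        for g in by_chrom.get(v.chrom, []):
            span = (g.exons[0][0] - SPLICE_FLANK, g.exons[-1][1] + SPLICE_FLANK)
            if v.pos <= span[1] and v.end >= span[0]:
                cand = classify(v, g, ref_genome)
                if cand.consequence != "noncoding":
                    call = cand
                    break
        out.append(call)
    return out


def consequence_summary(calls: Iterable[ConsequenceCall]) -> dict:
    """Counts per category plus percentages of the protein-altering total.

    Percentages are rounded half-up to one decimal and are ``None`` when
    there are no protein-altering calls (undefined, not zero).
    """
    counts = Counter(c.consequence for c in calls)
    full = {cat: counts.get(cat, 0) for cat in CATEGORIES}
    pa_total = sum(full[cat] for cat in PROTEIN_ALTERING)
    if pa_total:
        percents = {cat: percent(full[cat], pa_total) for cat in PROTEIN_ALTERING}
    else:
        percents = {cat: None for cat in PROTEIN_ALTERING}
    return {
        "counts": full,
        "protein_altering_total": pa_total,
        "percent_of_protein_altering": percents,
    }
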