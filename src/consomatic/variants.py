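"""Core variant representation, normalization and canonical keying.

All coordinates are 1-based and inclusive, matching the VCF/GFF convention;
any half-open arithmetic is internal only.  Variants are matched across
callers on their *normalized* representation (left-aligned, minimal), so
equivalent indel spellings from different callers collapse to one key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

_VALID_BASES = frozenset("ACGT")

#: The seven callers whose outputs the pipeline consolidates.
CALLERS = (
    "mutect",
    "jointsnvmix",
    "somaticsniper",
    "varscan",
    "somaticindeldetector",
    "pindel",
    "unifiedgenotyper",
)

#: Callers eligible to support an SNV under the >=2-caller consensus rule.
SNV_CALLERS = frozenset({"mutect", "jointsnvmix", "somaticsniper", "varscan", "unifiedgenotyper"})

#: Callers eligible to support an indel (any single one suffices).
INDEL_CALLERS = frozenset({"somaticindeldetector", "varscan", "pindel", "unifiedgenotyper"})

#: Callers that genotype tumor and germline separately rather than jointly.
GERMLINE_SEPARATE_CALLERS = frozenset({"pindel", "unifiedgenotyper"})

HISTOLOGY_GROUPS = ("benign", "borderline", "carcinoma")


class ReferenceMismatchError(ValueError):
    """The declared reference allele disagrees with the genome sequence."""


class CoordinateError(ValueError):
    """A position falls outside its contig."""


class NormalizationError(ValueError):
    """A variant is not in normalized (left-aligned, minimal) form."""


@dataclass(frozen=True)
class ReferenceGenome:
    """Reference sequence over {A,C,G,T,N}, addressed 1-based.

    Parameters
    ----------
    contigs
        Mapping of contig name to uppercase sequence.
    """

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def base(self, chrom: str, pos: int) -> str:
        """Single base at 1-based ``pos``."""
        return self.slice(chrom, pos, pos)

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive interval [start, end]."""
        try:
            seq = self.contigs[chrom]
        except KeyError:
            raise CoordinateError(f"unknown contig {chrom!r}") from None
        if start < 1 or end > len(seq) or start > end:
            raise CoordinateError(f"{chrom}:{start}-{end} outside contig of length {len(seq)}")
        return seq[start - 1 : end]


@dataclass(frozen=True, order=True)
class Variant:
    """A genomic change: ``chrom:pos ref>alt`` with 1-based leftmost position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be nonempty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def vclass(self) -> str:
        """``snv`` for single-base substitutions, ``indel`` otherwise."""
        return "snv" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def end(self) -> int:
        """Last reference base covered, 1-based inclusive."""
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class CallerCall:
    """One caller's observation of a variant with tumor/germline read evidence.

    Caller/vclass compatibility is deliberately not enforced here; the
    consensus stage decides which callers may support which variant class.
    """

    variant: Variant
    caller: str
    tumor_alt_reads: int
    tumor_depth: int
    germline_alt_reads: int
    germline_depth: int

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        for alt, depth, label in (
            (self.tumor_alt_reads, self.tumor_depth, "tumor"),
            (self.germline_alt_reads, self.germline_depth, "germline"),
        ):
            if not (0 <= alt <= depth):
                raise ValueError(f"{label}: require 0 <= alt_reads ({alt}) <= depth ({depth})")

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt_reads / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def germline_vaf(self) -> float:
        # depth 0 treated as 0% germline signal; the filter flags it low-confidence
        return self.germline_alt_reads / self.germline_depth if self.germline_depth else 0.0


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model: ordered exons plus CDS bounds.

    Intervals are 1-based closed.  One transcript per gene; isoform choice
    is out of scope for this pipeline.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene must have at least one exon")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon {start}-{end} has start > end")
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if not (self.exons[0][0] <= self.cds_start <= self.cds_end <= self.exons[-1][1]):
            raise ValueError("CDS bounds outside exon span")
        if not self._in_exons(self.cds_start) or not self._in_exons(self.cds_end):
            raise ValueError("CDS bounds must fall inside exons")
        if len(self.cds_positions()) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")

    def _in_exons(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def cds_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces clipped to the CDS, genomic order, 1-based closed."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 <= e2:
                out.append((s2, e2))
        return out

    def cds_positions(self) -> list[int]:
        """All genomic CDS positions in genomic order."""
        return [p for s, e in self.cds_intervals() for p in range(s, e + 1)]

    def splice_positions(self, flank: int = 2) -> set[int]:
        """Intronic positions within ``flank`` bp of an exon/intron boundary.

        Only internal boundaries count: the outermost exon edges border
        flanking sequence, not introns.
        """
        sites: set[int] = set()
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # acceptor side: intron bases just 5' of this exon
                sites.update(range(s - flank, s))
            if i < len(self.exons) - 1:  # donor side: intron bases just 3'
                sites.update(range(e + 1, e + 1 + flank))
        return sites

    def cds_sequence(self, ref_genome: ReferenceGenome) -> str:
        """Coding sequence in transcription order (reverse-complemented on '-')."""
        seq = "".join(ref_genome.slice(self.chrom, s, e) for s, e in self.cds_intervals())
        return _revcomp(seq) if self.strand == "-" else seq


@dataclass
class SamplePair:
    """A matched tumor/germline pair with its per-caller call sets."""

    tumor_id: str
    germline_id: str
    histology: str
    callsets: dict[str, list[CallerCall]] = field(default_factory=dict)
    territory_mb: float = 30.0

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGY_GROUPS:
            raise ValueError(f"histology must be one of {HISTOLOGY_GROUPS}")
        if self.territory_mb <= 0:
            raise ValueError("territory_mb must be > 0")

    def all_calls(self) -> Iterable[CallerCall]:
        for calls in self.callsets.values():
            yield from calls


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(v: Variant, ref_genome: ReferenceGenome) -> Variant:
    """Left-align and minimalize a variant against the reference.

    The normalized form has no shared allele suffix and a shared prefix of at
    most the single anchor base required by indels, placed at the leftmost
    equivalent position.  Normalization is idempotent and preserves the edit:
    applying the raw and the normalized variant to the reference yields the
    same sequence.

    Raises
    ------
    ReferenceMismatchError
        If ``v.ref`` disagrees with the genome at ``v.pos``.
    CoordinateError
        If the variant does not fit inside its contig.
    """
    observed = ref_genome.slice(v.chrom, v.pos, v.end)
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos} declared ref {v.ref!r} but genome has {observed!r}"
        )
    pos, ref, alt = v.pos, v.ref, v.alt
    # Left-align by repeated right-trim / left-extend (the standard VCF
    # normalization loop), then strip the redundant shared prefix.
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > 1:
            prev = ref_genome.base(v.chrom, pos - 1)
            if prev == "N":
                break
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return Variant(v.chrom, pos, ref, alt)


def is_minimal(v: Variant) -> bool:
    """Representational minimality check (no genome needed).

    True iff the alleles share no suffix and share a prefix only as the
    single anchor base of an indel.  Left-alignment additionally requires the
    genome and is guaranteed by :func:`normalize`.
    """
    if v.ref[-1] == v.alt[-1] and v.pos > 1:
        return False  # trimmable/left-shiftable shared suffix
    if len(v.ref) > 1 and len(v.alt) > 1 and v.ref[0] == v.alt[0]:
        return False  # shared prefix beyond the indel anchor
    return True


def variant_key(v: Variant) -> tuple[str, int, str, str]:
    """Canonical hashable key for cross-caller matching.

    Requires a minimal representation so that equal keys mean equal variants.
    """
    if not is_minimal(v):
        raise NormalizationError(f"variant {v} is not minimal; call normalize() first")
    return (v.chrom, v.pos, v.ref, v.alt)


def apply_variant(v: Variant, ref_genome: ReferenceGenome) -> str:
    """Contig sequence with the edit applied (test/verification helper)."""
    seq = ref_genome.contigs[v.chrom]
    if seq[v.pos - 1 : v.end] != v.ref:
        raise ReferenceMismatchError(f"ref mismatch at {v.chrom}:{v.pos}")
    return seq[: v.pos - 1] + v.alt + seq[v.end :]
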