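"""Mutation burden and substitution-spectrum profiling.

Substitutions are collapsed to the six pyrimidine-reference classes
(C>A, C>G, C>T, T>A, T>C, T>G): a change at a purine reference base is
reported as the complementary change, so G>A counts as C>T.  Trinucleotide
contexts are likewise pyrimidine-oriented, giving the standard 96 classes.
The CpG-deamination signature is tallied as C>T events whose central
cytosine is followed by a 3' guanine in pyrimidine orientation (NpCpG, the
optimum motif for spontaneous 5-methylcytosine deamination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Iterable, Sequence

from consomatic.variants import ReferenceGenome, Variant, _revcomp

SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 trinucleotide-change classes, as "5'[ref>alt]3'" strings.
CONTEXT_CLASSES = tuple(
    f"{five}[{cls}]{three}"
    for cls in SIX_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

HYPERMUTATOR_RATE = 10.0  # coding mutations per Mb


@dataclass
class SpectrumProfile:
    """Six-class and 96-context substitution counts with NpCpG tallies."""

    six_class_counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SIX_CLASSES})
    context_counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CONTEXT_CLASSES})
    n_substitutions: int = 0
    ct_at_cpg: int = 0
    n_context_excluded: int = 0  # contig-edge or N-context SNVs, kept in six-class only

    def six_class_fractions(self) -> dict[str, float | None]:
        n = self.n_substitutions
        return {c: (k / n if n else None) for c, k in self.six_class_counts.items()}


@dataclass(frozen=True)
class BurdenRecord:
    """Per-sample coding mutation burden."""

    sample_id: str
    histology: str
    n_coding_mutations: int
    territory_mb: float

    def __post_init__(self) -> None:
        if self.territory_mb <= 0:
            raise ValueError("territory_mb must be > 0")

    @property
    def mutations_per_mb(self) -> float:
        return self.n_coding_mutations / self.territory_mb

    @property
    def hypermutated(self) -> bool:
        return self.mutations_per_mb > HYPERMUTATOR_RATE


def substitution_class(variant: Variant, ref_genome: ReferenceGenome) -> str:
    """Pyrimidine-collapsed class of an SNV (G>A reported as C>T, etc.)."""
    if variant.vclass != "snv":
        raise ValueError(f"substitution_class requires an SNV, got {variant}")
    ref = ref_genome.base(variant.chrom, variant.pos)
    if ref != variant.ref:
        raise ValueError(f"reference mismatch at {variant.chrom}:{variant.pos}")
    ref_b, alt_b = variant.ref, variant.alt
    if ref_b in "AG":  # collapse purine reference onto the complementary strand
        ref_b, alt_b = _revcomp(ref_b), _revcomp(alt_b)
    return f"{ref_b}>{alt_b}"


def trinucleotide_context(variant: Variant, ref_genome: ReferenceGenome) -> tuple[str, bool] | None:
    """Pyrimidine-oriented 3-mer context of an SNV and its CpG flag.

    Returns ``None`` for SNVs at a contig edge or with an N in the 3-mer;
    such events are excluded from context counts but still counted in the
    six-class spectrum.  The CpG flag is true iff the (oriented) central C
    is followed by a 3' G — the NpCpG deamination motif.
    """
    if variant.vclass != "snv":
        raise ValueError("trinucleotide_context requires an SNV")
    length = ref_genome.lengths[variant.chrom]
    if variant.pos == 1 or variant.pos == length:
        return None
    trimer = ref_genome.slice(variant.chrom, variant.pos - 1, variant.pos + 1)
    if "N" in trimer:
        return None
    if variant.ref in "AG":
        trimer = _revcomp(trimer)
    cpg = trimer[1] == "C" and trimer[2] == "G"
    return trimer, cpg


def spectrum_profile(variants: Iterable[Variant], ref_genome: ReferenceGenome) -> SpectrumProfile:
    """Aggregate SNVs into a :class:`SpectrumProfile`; indels are ignored."""
    profile = SpectrumProfile()
    for v in variants:
        if v.vclass != "snv":
            continue
        cls = substitution_class(v, ref_genome)
        profile.six_class_counts[cls] += 1
        profile.n_substitutions += 1
        ctx = trinucleotide_context(v, ref_genome)
        if ctx is None:
            profile.n_context_excluded += 1
            continue
        trimer, cpg = ctx
        profile.context_counts[f"{trimer[0]}[{cls}]{trimer[2]}"] += 1
        if cls == "C>T" and cpg:
            profile.ct_at_cpg += 1
    return profile


def npcpg_fraction(profile: SpectrumProfile) -> dict[str, float | None]:
    """NpCpG C>T fractions: among C>T events and among all substitutions.

    Fractions are ``None`` (undefined) when their denominator is zero.
    """
    n_ct = profile.six_class_counts["C>T"]
    return {
        "of_ct": profile.ct_at_cpg / n_ct if n_ct else None,
        "of_all": profile.ct_at_cpg / profile.n_substitutions if profile.n_substitutions else None,
    }


def burden(sample_id: str, histology: str, variants: Sequence[Variant], territory_mb: float) -> BurdenRecord:
    """Coding mutation burden for one sample over its callable territory."""
    return BurdenRecord(
        sample_id=sample_id,
        histology=histology,
        n_coding_mutations=len(variants),
        territory_mb=territory_mb,
    )


def group_burden(records: Sequence[BurdenRecord]) -> dict[str, dict]:
    """Per-histology burden summary: mean count, count range, pooled rate.

    The pooled rate is total mutations over total territory, not the mean of
    per-sample rates — group rates in heterogeneous-territory cohorts are
    not simple averages.
    """
    groups: dict[str, list[BurdenRecord]] = {}
    for r in records:
        groups.setdefault(r.histology, []).append(r)
    out = {}
    for name, recs in groups.items():
        counts = [r.n_coding_mutations for r in recs]
        out[name] = {
            "n_samples": len(recs),
            "mean_mutations": sum(counts) / len(counts),
            "range": (min(counts), max(counts)),
            "mutations_per_mb": sum(counts) / sum(r.territory_mb for r in recs),
            "n_hypermutated": sum(r.hypermutated for r in recs),
        }
    return out


def cpg_opportunity_fraction(ref_genome: ReferenceGenome) -> float:
    """Fraction of C:G sites that sit in a CpG dinucleotide context.

    Scans every contig once; used to check that an unweighted simulation
    produces C>T@CpG at its opportunity rate.
    """
    cg_sites = 0
    cpg_sites = 0
    for seq in ref_genome.contigs.values():
        for i, base in enumerate(seq):
            if base == "C":
                cg_sites += 1
                if i + 1 < len(seq) and seq[i + 1] == "G":
                    cpg_sites += 1
            elif base == "G":
                cg_sites += 1
                if i > 0 and seq[i - 1] == "C":
                    cpg_sites += 1
    return cpg_sites / cg_sites if cg_sites else 0.0
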