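"""Synthetic tumor/normal cohort with a known truth set.

Protected patient data cannot ship with a pipeline, so every downstream
stage is exercised on a simulated cohort instead: a small random reference
("mini-exome" of tiled single-transcript genes), true somatic SNVs/indels
drawn with a CpG-deamination-weighted substitution signature, germline SNPs
drawn from a shared population catalog (so panel-of-normals and
population-frequency rules have real hits), and per-caller call sets that
emulate the sensitivity, false-positive and germline-leakage behavior of
the seven callers the consolidation cascade consumes.

Physical coordinates live on small contigs, but each pair carries a nominal
``territory_mb`` (callable exome size); somatic mutation counts are Poisson
with mean ``burden_per_mb * territory_mb``, so per-sample counts and
mutations/Mb match full-exome study conditions while sequences stay small.
All randomness flows from a single seeded generator: identical configs give
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from consomatic import io as cio
from consomatic.variants import (
    CALLERS,
    CallerCall,
    GeneModel,
    HISTOLOGY_GROUPS,
    ReferenceGenome,
    SamplePair,
    Variant,
    normalize,
    variant_key,
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic cohort; the seed fixes outputs bit-for-bit."""

    seed: int = 0
    # reference
    n_contigs: int = 2
    contig_length: int = 400_000
    gc_fraction: float = 0.45
    # gene models
    n_genes: int = 220
    exons_per_gene: int = 4
    exon_length: int = 150
    intron_length: int = 200
    intergenic_gap: int = 300
    # cohort composition (discovery-cohort shape: 5 benign / 8 borderline / 11 carcinoma)
    n_pairs: Mapping[str, int] = field(
        default_factory=lambda: {"benign": 5, "borderline": 8, "carcinoma": 11}
    )
    # somatic burden: rate/Mb per group times a global multiplier, over a
    # nominal per-group callable territory (count = rate x territory)
    somatic_burden_per_mb: float = 1.0
    burden_per_mb_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"benign": 0.8, "borderline": 0.9, "carcinoma": 1.5}
    )
    territory_mb_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"benign": 31.75, "borderline": 36.5, "carcinoma": 44.6}
    )
    # substitution signature
    cpg_ct_weight: float = 8.0
    transition_weight: float = 2.0
    indel_fraction: float = 0.084
    max_indel_length: int = 6
    # germline polymorphism
    germline_snp_rate: float = 5e-4
    germline_indel_fraction: float = 0.05
    popfreq_known_fraction: float = 0.9
    external_panel_size: int = 147
    # read model
    mean_depth: float = 144.0
    depth_dispersion: float = 26.0
    tumor_vaf_mean: float = 0.35
    tumor_vaf_concentration: float = 20.0
    germline_noise_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ValueError("reference must have at least one nonempty contig")
        for name in ("gc_fraction", "indel_fraction", "germline_indel_fraction",
                     "popfreq_known_fraction", "tumor_vaf_mean", "germline_noise_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.cpg_ct_weight < 1.0:
            raise ValueError("cpg_ct_weight >= 1 is required for an NpCpG-enriched spectrum")
        for group in self.n_pairs:
            if group not in HISTOLOGY_GROUPS:
                raise ValueError(f"unknown histology group {group!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["n_pairs"] = dict(d["n_pairs"])
        d["burden_per_mb_by_group"] = dict(d["burden_per_mb_by_group"])
        d["territory_mb_by_group"] = dict(d["territory_mb_by_group"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class CallerProfile:
    """Emulated detection behavior of one caller."""

    caller: str
    handles_snv: bool
    handles_indel: bool
    sens_snv: float = 0.0
    sens_indel: float = 0.0
    fp_per_mb: float = 0.0
    calls_germline_separately: bool = False

    def __post_init__(self) -> None:
        for p in (self.sens_snv, self.sens_indel):
            if not (0.0 <= p <= 1.0):
                raise ValueError("sensitivities must be probabilities")
        if self.fp_per_mb < 0:
            raise ValueError("fp_per_mb must be nonnegative")


def default_caller_profiles() -> dict[str, CallerProfile]:
    """Plausible per-caller operating points for the seven emulated callers.

    SNV-only, indel-only and dual-class callers follow each tool's actual
    scope; pindel and unifiedgenotyper genotype tumor and germline
    separately and therefore leak germline variants into the tumor call set
    (which the germline-fraction rules must remove).
    """
    return {
        "mutect": CallerProfile("mutect", True, False, sens_snv=0.97, fp_per_mb=20),
        "jointsnvmix": CallerProfile("jointsnvmix", True, False, sens_snv=0.95, fp_per_mb=30),
        "somaticsniper": CallerProfile("somaticsniper", True, False, sens_snv=0.90, fp_per_mb=30),
        "varscan": CallerProfile("varscan", True, True, sens_snv=0.92, sens_indel=0.80, fp_per_mb=15),
        "somaticindeldetector": CallerProfile(
            "somaticindeldetector", False, True, sens_indel=0.85, fp_per_mb=3
        ),
        "pindel": CallerProfile(
            "pindel", False, True, sens_indel=0.90, fp_per_mb=5, calls_germline_separately=True
        ),
        "unifiedgenotyper": CallerProfile(
            "unifiedgenotyper", True, True, sens_snv=0.90, sens_indel=0.80,
            fp_per_mb=25, calls_germline_separately=True,
        ),
    }


@dataclass(frozen=True)
class TruthVariant:
    variant: Variant
    origin: str  # somatic | germline
    true_tumor_vaf: float
    true_germline_vaf: float
    in_coding: bool
    pop_maf: float = 0.0

    def __post_init__(self) -> None:
        if self.origin not in ("somatic", "germline"):
            raise ValueError("origin must be somatic or germline")
        if self.origin == "somatic" and self.true_germline_vaf != 0.0:
            raise ValueError("somatic truth must have zero germline VAF")
        if self.origin == "germline" and self.true_germline_vaf not in (0.5, 1.0):
            raise ValueError("germline truth must be het (0.5) or hom (1.0)")


@dataclass
class PairTruth:
    tumor_id: str
    germline_id: str
    histology: str
    territory_mb: float
    variants: list[TruthVariant] = field(default_factory=list)


@dataclass
class TruthSet:
    """Gold standard: per-pair truth plus panel and population catalogs."""

    pairs: dict[str, PairTruth] = field(default_factory=dict)
    panel_counts: dict[tuple, int] = field(default_factory=dict)  # external panel carriers
    pop_freq: dict[tuple, float] = field(default_factory=dict)  # known population MAFs


@dataclass
class Cohort:
    """A fully materialized synthetic cohort."""

    config: SimConfig
    ref_genome: ReferenceGenome
    genes: list[GeneModel]
    truth: TruthSet
    pairs: list[SamplePair]
    panel_germline: dict[str, list[CallerCall]]  # germline-only records per sample


# ---------------------------------------------------------------------------
# Reference and gene models

def generate_reference(cfg: SimConfig, rng: np.random.Generator | None = None) -> ReferenceGenome:
    """Random reference with the configured GC fraction, deterministic under seed."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    gc = cfg.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    contigs = {}
    for i in range(cfg.n_contigs):
        seq = rng.choice(bases, size=cfg.contig_length, p=p)
        contigs[f"chr{i + 1}"] = "".join(seq)
    return ReferenceGenome(contigs)


def generate_gene_models(
    cfg: SimConfig, ref_genome: ReferenceGenome, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Tile single-transcript genes across the contigs.

    Each gene has ``exons_per_gene`` exons of ``exon_length`` bp separated
    by fixed-length introns; the CDS covers the exon span, trimmed at the 3'
    end so its length is divisible by 3.  Raises if the requested genes do
    not fit.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    gene_span = cfg.exons_per_gene * cfg.exon_length + (cfg.exons_per_gene - 1) * cfg.intron_length
    slot = gene_span + cfg.intergenic_gap
    names = list(ref_genome.contigs)
    capacity = {c: (len(ref_genome.contigs[c]) - cfg.intergenic_gap) // slot for c in names}
    if sum(capacity.values()) < cfg.n_genes:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes of span {gene_span} bp into the reference"
        )
    genes = []
    contig_idx, placed_on = 0, {c: 0 for c in names}
    for gi in range(cfg.n_genes):
        while placed_on[names[contig_idx]] >= capacity[names[contig_idx]]:
            contig_idx = (contig_idx + 1) % len(names)
        chrom = names[contig_idx]
        start = cfg.intergenic_gap + placed_on[chrom] * slot + 1
        placed_on[chrom] += 1
        contig_idx = (contig_idx + 1) % len(names)
        exons = []
        pos = start
        for _ in range(cfg.exons_per_gene):
            exons.append((pos, pos + cfg.exon_length - 1))
            pos += cfg.exon_length + cfg.intron_length
        cds_len = cfg.exons_per_gene * cfg.exon_length
        trim = cds_len % 3
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:04d}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=exons[0][0],
                cds_end=exons[-1][1] - trim,
            )
        )
    return genes


def cds_territory_mb(genes: Sequence[GeneModel]) -> float:
    """Physical CDS territory of the gene models, in Mb."""
    return sum(len(g.cds_positions()) for g in genes) / 1e6


# ---------------------------------------------------------------------------
# Truth simulation

_TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _alt_weights(ref_base: str, is_cpg_c: bool, cfg: SimConfig) -> tuple[list[str], list[float]]:
    """Substitution weights: transition bias plus a C>T boost at CpG cytosines.

    ``is_cpg_c`` means the site is a cytosine of a CpG dinucleotide in
    pyrimidine orientation (C followed by G, or G preceded by C).
    """
    alts = [b for b in "ACGT" if b != ref_base]
    weights = []
    for alt in alts:
        w = cfg.transition_weight if alt == _TRANSITIONS[ref_base] else 1.0
        if is_cpg_c and ref_base in "CG" and alt == _TRANSITIONS[ref_base]:
            w *= cfg.cpg_ct_weight
        weights.append(w)
    return alts, weights


def _sample_snv_alt(ref_base: str, is_cpg_c: bool, cfg: SimConfig, rng: np.random.Generator) -> str:
    alts, weights = _alt_weights(ref_base, is_cpg_c, cfg)
    p = np.array(weights) / sum(weights)
    return alts[rng.choice(3, p=p)]


def _sample_weighted_snv(
    cds_sites: Sequence[tuple[str, int]],
    ref_genome: ReferenceGenome,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Variant:
    """Draw a somatic SNV from the joint (site, substitution) weight model.

    Sites and alternate bases are sampled together, each (site, alt) pair
    weighted by the signature, so ``cpg_ct_weight`` both concentrates events
    at CpG cytosines and tilts them toward C>T — the mutational footprint of
    5-methylcytosine deamination.  Rejection sampling keeps the draw exact.
    """
    max_total = 2.0 + cfg.transition_weight * cfg.cpg_ct_weight
    while True:
        chrom, pos = cds_sites[int(rng.integers(0, len(cds_sites)))]
        seq = ref_genome.contigs[chrom]
        ref_base = seq[pos - 1]
        if ref_base == "N":
            continue
        alts, weights = _alt_weights(ref_base, _is_cpg_site(seq, pos - 1), cfg)
        total = sum(weights)
        if rng.random() * max_total > total:
            continue
        p = np.array(weights) / total
        return Variant(chrom, pos, ref_base, alts[rng.choice(3, p=p)])


def _is_cpg_site(seq: str, idx0: int) -> bool:
    base = seq[idx0]
    if base == "C":
        return idx0 + 1 < len(seq) and seq[idx0 + 1] == "G"
    if base == "G":
        return idx0 > 0 and seq[idx0 - 1] == "C"
    return False


def _random_indel(
    chrom: str, pos: int, seq: str, cfg: SimConfig, rng: np.random.Generator
) -> Variant | None:
    length = int(rng.integers(1, cfg.max_indel_length + 1))
    anchor = seq[pos - 1]
    if rng.random() < 0.5 and pos + length <= len(seq):  # deletion
        ref = seq[pos - 1 : pos + length]
        if "N" in ref:
            return None
        return Variant(chrom, pos, ref, anchor)
    ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return Variant(chrom, pos, anchor, anchor + ins)


def simulate_truth(
    cfg: SimConfig,
    ref_genome: ReferenceGenome,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Draw the cohort's true somatic and germline variants.

    Somatic counts per pair are Poisson with mean burden x territory; sites
    are uniform over the coding territory; substitutions follow the
    CpG-weighted signature; the configured fraction are indels.  Germline
    variants come from a shared population catalog whose minor allele
    frequencies drive genotypes, the external panel counts, and the known
    population-frequency table.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    truth = TruthSet()

    genome_len = sum(ref_genome.lengths.values())
    contig_names = list(ref_genome.contigs)
    cds_sites = [(g.chrom, p) for g in genes for p in g.cds_positions()]

    # --- population catalog of germline polymorphisms
    mean_carrier = 0.425  # E[f(2-f)] for f ~ U(0.01, 0.5)
    n_catalog = int(round(cfg.germline_snp_rate * genome_len / mean_carrier))
    catalog: list[tuple[Variant, float]] = []
    used_keys: set[tuple] = set()
    for _ in range(n_catalog):
        chrom = contig_names[int(rng.integers(0, len(contig_names)))]
        seq = ref_genome.contigs[chrom]
        pos = int(rng.integers(2, len(seq)))  # keep off contig edges
        maf = float(rng.uniform(0.01, 0.5))
        if rng.random() < cfg.germline_indel_fraction:
            v = _random_indel(chrom, pos, seq, cfg, rng)
        else:
            ref_base = seq[pos - 1]
            if ref_base == "N":
                continue
            v = Variant(chrom, pos, ref_base, _sample_snv_alt(ref_base, False, cfg, rng))
        if v is None:
            continue
        v = normalize(v, ref_genome)
        key = variant_key(v)
        if key in used_keys:
            continue
        used_keys.add(key)
        catalog.append((v, maf))
        carrier = maf * (2 - maf)
        truth.panel_counts[key] = int(rng.binomial(cfg.external_panel_size, carrier))
        if rng.random() < cfg.popfreq_known_fraction:
            truth.pop_freq[key] = round(maf, 4)

    # --- per-pair truth
    cds_index = {(c, p): i for i, (c, p) in enumerate(cds_sites)}
    pair_no = 0
    for group in HISTOLOGY_GROUPS:
        burden = cfg.burden_per_mb_by_group.get(group, 1.0) * cfg.somatic_burden_per_mb
        territory = cfg.territory_mb_by_group.get(group, cds_territory_mb(genes))
        for _ in range(cfg.n_pairs.get(group, 0)):
            pair_no += 1
            tumor_id, germline_id = f"T{pair_no:02d}", f"N{pair_no:02d}"
            pt = PairTruth(tumor_id, germline_id, group, territory)

            for v, maf in catalog:
                r = rng.random()
                het, hom = 2 * maf * (1 - maf), maf * maf
                if r < het:
                    gvaf = 0.5
                elif r < het + hom:
                    gvaf = 1.0
                else:
                    continue
                key = variant_key(v)
                pt.variants.append(
                    TruthVariant(
                        variant=v,
                        origin="germline",
                        true_tumor_vaf=gvaf,
                        true_germline_vaf=gvaf,
                        in_coding=(v.chrom, v.pos) in cds_index,
                        pop_maf=truth.pop_freq.get(key, 0.0),
                    )
                )

            n_somatic = int(rng.poisson(burden * territory))
            pair_keys = {variant_key(t.variant) for t in pt.variants}
            for _ in range(n_somatic):
                for _attempt in range(20):
                    if rng.random() < cfg.indel_fraction:
                        chrom, pos = cds_sites[int(rng.integers(0, len(cds_sites)))]
                        v = _random_indel(chrom, pos, ref_genome.contigs[chrom], cfg, rng)
                    else:
                        v = _sample_weighted_snv(cds_sites, ref_genome, cfg, rng)
                    if v is None:
                        continue
                    v = normalize(v, ref_genome)
                    key = variant_key(v)
                    if key in pair_keys:
                        continue
                    pair_keys.add(key)
                    vaf_a = cfg.tumor_vaf_mean * cfg.tumor_vaf_concentration
                    vaf_b = (1 - cfg.tumor_vaf_mean) * cfg.tumor_vaf_concentration
                    pt.variants.append(
                        TruthVariant(
                            variant=v,
                            origin="somatic",
                            true_tumor_vaf=float(rng.beta(vaf_a, vaf_b)),
                            true_germline_vaf=0.0,
                            in_coding=True,
                            pop_maf=0.0,
                        )
                    )
                    break
            truth.pairs[tumor_id] = pt
    return truth


# ---------------------------------------------------------------------------
# Caller emulation

def expected_consensus_snv_sensitivity(sensitivities: Sequence[float]) -> float:
    """Closed-form P(>=2 of the independent SNV callers detect a variant)."""
    s = np.asarray(sensitivities, float)
    none = np.prod(1 - s)
    exactly_one = sum(s[i] * np.prod(np.delete(1 - s, i)) for i in range(len(s)))
    return float(1 - none - exactly_one)


def _depth(cfg: SimConfig, rng: np.random.Generator) -> int:
    r = cfg.depth_dispersion
    p = r / (r + cfg.mean_depth)
    return max(int(rng.negative_binomial(r, p)), 1)


def emulate_calls(
    truth: TruthSet,
    profiles: Mapping[str, CallerProfile],
    cfg: SimConfig,
    ref_genome: ReferenceGenome,
    rng: np.random.Generator | None = None,
) -> tuple[list[SamplePair], dict[str, list[CallerCall]]]:
    """Emulate the seven callers on the truth set.

    Returns the per-pair :class:`SamplePair` objects (with per-caller call
    sets) and per-germline panel records.  True variants of a class a
    caller handles are detected with its class sensitivity; read depths and
    allele counts come from the negative-binomial/binomial read model;
    tumor/germline-separate callers additionally report germline variants
    in the tumor; false positives are placed uniformly genome-wide at each
    caller's rate.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    missing = set(CALLERS) - set(profiles)
    if missing:
        raise ValueError(f"caller profiles missing: {sorted(missing)}")

    contig_names = list(ref_genome.contigs)
    genome_mb = sum(ref_genome.lengths.values()) / 1e6
    pairs: list[SamplePair] = []
    panel: dict[str, list[CallerCall]] = {}

    for tumor_id in sorted(truth.pairs):
        pt = truth.pairs[tumor_id]
        callsets: dict[str, list[CallerCall]] = {c: [] for c in CALLERS}
        germline_records: list[CallerCall] = []

        for tv in pt.variants:
            t_depth, g_depth = _depth(cfg, rng), _depth(cfg, rng)
            t_alt = int(rng.binomial(t_depth, tv.true_tumor_vaf))
            if tv.origin == "somatic":
                g_alt = int(rng.binomial(g_depth, cfg.germline_noise_rate))
            else:
                g_alt = int(rng.binomial(g_depth, tv.true_germline_vaf))
            vclass = tv.variant.vclass
            if tv.origin == "germline":
                germline_records.append(
                    CallerCall(tv.variant, "unifiedgenotyper", g_alt, g_depth, g_alt, g_depth)
                )
            for caller in CALLERS:
                prof = profiles[caller]
                handles = prof.handles_snv if vclass == "snv" else prof.handles_indel
                if not handles:
                    continue
                if tv.origin == "germline" and not prof.calls_germline_separately:
                    continue  # joint callers subtract the matched germline
                sens = prof.sens_snv if vclass == "snv" else prof.sens_indel
                if rng.random() < sens:
                    callsets[caller].append(
                        CallerCall(tv.variant, caller, t_alt, t_depth, g_alt, g_depth)
                    )

        truth_keys = {variant_key(t.variant) for t in pt.variants}
        for caller in CALLERS:
            prof = profiles[caller]
            n_fp = int(rng.poisson(prof.fp_per_mb * genome_mb))
            for _ in range(n_fp):
                chrom = contig_names[int(rng.integers(0, len(contig_names)))]
                seq = ref_genome.contigs[chrom]
                pos = int(rng.integers(2, len(seq)))
                make_snv = prof.handles_snv and (not prof.handles_indel or rng.random() < 0.9)
                if make_snv:
                    ref_base = seq[pos - 1]
                    if ref_base == "N":
                        continue
                    alts = [b for b in "ACGT" if b != ref_base]
                    v = Variant(chrom, pos, ref_base, alts[int(rng.integers(0, 3))])
                else:
                    v = _random_indel(chrom, pos, seq, cfg, rng)
                    if v is None:
                        continue
                v = normalize(v, ref_genome)
                key = variant_key(v)
                if key in truth_keys:
                    continue
                t_depth, g_depth = _depth(cfg, rng), _depth(cfg, rng)
                fp_vaf = float(rng.beta(1.2, 25.0))
                t_alt = min(max(int(rng.binomial(t_depth, fp_vaf)), 1), t_depth)
                g_alt = int(rng.binomial(g_depth, cfg.germline_noise_rate))
                callsets[caller].append(CallerCall(v, caller, t_alt, t_depth, g_alt, g_depth))

        pairs.append(
            SamplePair(
                tumor_id=pt.tumor_id,
                germline_id=pt.germline_id,
                histology=pt.histology,
                callsets=callsets,
                territory_mb=pt.territory_mb,
            )
        )
        panel[pt.germline_id] = germline_records
    return pairs, panel


# ---------------------------------------------------------------------------
# Orchestration and cohort I/O

def simulate_cohort(cfg: SimConfig, profiles: Mapping[str, CallerProfile] | None = None) -> Cohort:
    """Generate the full cohort from one seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    ref_genome = generate_reference(cfg, rng)
    genes = generate_gene_models(cfg, ref_genome, rng)
    truth = simulate_truth(cfg, ref_genome, genes, rng)
    pairs, panel = emulate_calls(truth, profiles or default_caller_profiles(), cfg, ref_genome, rng)
    return Cohort(config=cfg, ref_genome=ref_genome, genes=genes, truth=truth, pairs=pairs, panel_germline=panel)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as plain-text files (FASTA, GFF3, VCFs, TSVs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = cohort.ref_genome.lengths

    cio.write_fasta(cohort.ref_genome, outdir / "reference.fa")
    cio.write_gene_models(cohort.genes, outdir / "genes.gff3")
    cohort.config.to_yaml(outdir / "config.yaml")

    pairs_dir = outdir / "pairs"
    for pair in cohort.pairs:
        pdir = pairs_dir / pair.tumor_id
        pdir.mkdir(parents=True, exist_ok=True)
        for caller, calls in pair.callsets.items():
            cio.write_caller_vcf(calls, pdir / f"{caller}.vcf", caller, lengths)

    panel_dir = outdir / "panel"
    panel_dir.mkdir(exist_ok=True)
    for germline_id, records in cohort.panel_germline.items():
        cio.write_caller_vcf(records, panel_dir / f"{germline_id}.vcf", "unifiedgenotyper", lengths)

    cio.write_popfreq(cohort.truth.pop_freq, outdir / "popfreq.tsv")
    cio.write_panel_counts(cohort.truth.panel_counts, outdir / "panel_external.tsv")

    with open(outdir / "metadata.tsv", "w") as fh:
        fh.write("tumor_id\tgermline_id\thistology\tterritory_mb\n")
        for pair in cohort.pairs:
            fh.write(f"{pair.tumor_id}\t{pair.germline_id}\t{pair.histology}\t{pair.territory_mb}\n")

    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "tumor_id\tchrom\tpos\tref\talt\tvclass\torigin\ttrue_tumor_vaf\t"
            "true_germline_vaf\tin_coding\tpop_maf\n"
        )
        for tumor_id in sorted(cohort.truth.pairs):
            for tv in cohort.truth.pairs[tumor_id].variants:
                v = tv.variant
                fh.write(
                    f"{tumor_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vclass}\t{tv.origin}\t"
                    f"{tv.true_tumor_vaf:.4f}\t{tv.true_germline_vaf}\t{int(tv.in_coding)}\t{tv.pop_maf}\n"
                )
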