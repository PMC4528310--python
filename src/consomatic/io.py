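"""File formats: FASTA reference, per-caller VCF, gene models, result tables.

The caller VCF dialect is deliberately uniform across the seven callers: one
VCF 4.2 file per caller per pair, sample columns TUMOR and GERMLINE, FORMAT
fields AD (per-allele read counts, Number=R) and DP, and the caller identity
in a ``##caller=`` header line.  The consolidation logic depends only on
call presence and read counts, so emulating seven real caller formats would
add nothing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from consomatic.variants import CallerCall, GeneModel, ReferenceGenome, Variant


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(ref_genome: ReferenceGenome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in ref_genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> ReferenceGenome:
    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    contigs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return ReferenceGenome(contigs)


# ---------------------------------------------------------------------------
# Caller VCFs

@dataclasses.dataclass
class VcfReadResult:
    """Parsed calls plus an audit of records that could not be used."""

    calls: list[CallerCall]
    caller: str
    flagged: list[tuple[int, str]]  # (1-based line number, reason)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def _vcf_header(caller: str, contig_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_meta("caller", caller)
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.formats.add("AD", "R", "Integer", "Per-allele read depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.add_sample("TUMOR")
    header.add_sample("GERMLINE")
    return header


def write_caller_vcf(
    calls: Sequence[CallerCall],
    path: str | Path,
    caller: str,
    contig_lengths: dict[str, int],
) -> None:
    """Write one caller's calls, sorted by coordinate for determinism."""
    header = _vcf_header(caller, contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in sorted(calls, key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt)):
            v = call.variant
            rec = vf.new_record(
                contig=v.chrom,
                start=v.pos - 1,  # pysam is 0-based internally
                alleles=(v.ref, v.alt),
            )
            rec.samples["TUMOR"]["AD"] = (call.tumor_depth - call.tumor_alt_reads, call.tumor_alt_reads)
            rec.samples["TUMOR"]["DP"] = call.tumor_depth
            rec.samples["GERMLINE"]["AD"] = (
                call.germline_depth - call.germline_alt_reads,
                call.germline_alt_reads,
            )
            rec.samples["GERMLINE"]["DP"] = call.germline_depth
            vf.write(rec)


def read_caller_vcf(path: str | Path, caller: str | None = None) -> VcfReadResult:
    """Read a caller VCF into :class:`CallerCall` records.

    Multi-allelic records are split into one call per alternate allele, with
    AD giving each allele's supporting reads.  Records with missing or
    inconsistent depth fields are flagged with their line number rather than
    silently dropped.
    """
    with pysam.VariantFile(str(path)) as vf:
        header_caller = None
        for rec in vf.header.records:
            if rec.key == "caller":
                header_caller = rec.value
        if caller is None:
            caller = header_caller
        if caller is None:
            raise ValueError(f"{path}: no ##caller= header line and no caller given")
        with open(path) as raw:
            n_header = 0
            for line in raw:
                if not line.startswith("#"):
                    break
                n_header += 1
        calls: list[CallerCall] = []
        flagged: list[tuple[int, str]] = []
        for idx, rec in enumerate(vf):
            line_no = n_header + 1 + idx
            try:
                tumor, germ = rec.samples["TUMOR"], rec.samples["GERMLINE"]
                t_ad, g_ad = tumor.get("AD"), germ.get("AD")
                t_dp, g_dp = tumor.get("DP"), germ.get("DP")
                if t_ad is None or g_ad is None or t_dp is None or g_dp is None:
                    flagged.append((line_no, "missing AD/DP fields"))
                    continue
                for alt_idx, alt in enumerate(rec.alts or (), start=1):
                    variant = Variant(rec.chrom, rec.pos, rec.ref, alt)
                    calls.append(
                        CallerCall(
                            variant=variant,
                            caller=caller,
                            tumor_alt_reads=t_ad[alt_idx],
                            tumor_depth=t_dp,
                            germline_alt_reads=g_ad[alt_idx],
                            germline_depth=g_dp,
                        )
                    )
            except (ValueError, KeyError, IndexError, TypeError) as exc:
                flagged.append((line_no, str(exc)))
    return VcfReadResult(calls=calls, caller=caller, flagged=flagged)


# ---------------------------------------------------------------------------
# Gene models (minimal single-transcript GFF3)

def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = (g.exons[0][0], g.exons[-1][1])
            fh.write(
                f"{g.chrom}\tconsomatic\tgene\t{span[0]}\t{span[1]}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tconsomatic\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={g.gene_id}\n")
            fh.write(
                f"{g.chrom}\tconsomatic\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t{g.strand}\t.\tParent={g.gene_id}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse the minimal GFF3 dialect written by :func:`write_gene_models`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": [], "cds": None}
                order.append(gid)
            elif ftype == "exon":
                genes[attr["Parent"]]["exons"].append((int(start), int(end)))
            elif ftype == "CDS":
                genes[attr["Parent"]]["cds"] = (int(start), int(end))
    out = []
    for gid in order:
        g = genes[gid]
        if g["cds"] is None:
            raise ValueError(f"gene {gid} has no CDS feature")
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
                cds_start=g["cds"][0],
                cds_end=g["cds"][1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Variant/decision tables

TABLE_COLUMNS = ["chrom", "pos", "ref", "alt", "vclass", "callers", "decision", "failed_rules"]


def write_variant_table(decisions: Iterable, path: str | Path) -> None:
    """Write filter decisions as a fixed-column TSV audit table."""
    rows = []
    for d in decisions:
        v = d.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "callers": ",".join(sorted(d.supporting_callers)),
                "decision": "retained" if d.retained else "rejected",
                "failed_rules": ",".join(d.failed_rules),
            }
        )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "pos": int, "ref": str, "alt": str},
        keep_default_na=False,
    )
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_popfreq(path: str | Path) -> dict[tuple[str, int, str, str], float]:
    """Population allele frequencies keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): float(r.maf)
        for r in df.itertuples(index=False)
    }


def write_popfreq(pop_freq: dict[tuple[str, int, str, str], float], path: str | Path) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "maf": maf}
        for k, maf in sorted(pop_freq.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"]).to_csv(path, sep="\t", index=False)


def read_panel_counts(path: str | Path) -> dict[tuple[str, int, str, str], int]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (r.chrom, int(r.pos), r.ref, r.alt): int(r.count)
        for r in df.itertuples(index=False)
    }


def write_panel_counts(counts: dict[tuple[str, int, str, str], int], path: str | Path) -> None:
    rows = [
        {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "count": n}
        for k, n in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "count"]).to_csv(path, sep="\t", index=False)
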