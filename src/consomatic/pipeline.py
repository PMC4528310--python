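"""End-to-end orchestration: cohort directory in, landscape report out.

Stages: (optional) simulate -> consolidate -> annotate -> spectrum -> stats
-> report.  All outputs are plain TSV/JSON/Markdown with no timestamps, so
a rerun under the same seed and config is byte-identical; the manifest
records the config hash and a checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path

import pandas as pd

from consomatic import io as cio
from consomatic.consequence import annotate as annotate_variants
from consomatic.filtering import (
    FilterConfig,
    cohort_panel_counts,
    consolidate,
    evaluate_against_truth,
    filter_funnel,
)
from consomatic.simulate import SimConfig, TruthVariant, simulate_cohort, write_cohort
from consomatic.spectrum import (
    SIX_CLASSES,
    CONTEXT_CLASSES,
    burden,
    group_burden,
    npcpg_fraction,
    spectrum_profile,
)
from consomatic.stats import chi_square, fisher_exact_2x2, rank_sum, recurrence_table
from consomatic.variants import (
    CALLERS,
    SamplePair,
    Variant,
    normalize,
    variant_key,
)

log = logging.getLogger("consomatic")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def load_cohort_dir(cohort_dir: str | Path):
    """Load a cohort directory written by :func:`consomatic.simulate.write_cohort`.

    Calls are normalized at load; variants whose reference span contains N
    are rejected (their trinucleotide context is undefined) and counted.
    """
    cohort_dir = Path(cohort_dir)
    ref_genome = cio.read_fasta(cohort_dir / "reference.fa")
    genes = cio.read_gene_models(cohort_dir / "genes.gff3")
    meta = pd.read_csv(cohort_dir / "metadata.tsv", sep="\t")
    pop_freq = cio.read_popfreq(cohort_dir / "popfreq.tsv")
    external_counts = cio.read_panel_counts(cohort_dir / "panel_external.tsv")

    pairs = []
    n_rejected_n = 0
    for row in meta.itertuples(index=False):
        callsets = {}
        for caller in CALLERS:
            path = cohort_dir / "pairs" / row.tumor_id / f"{caller}.vcf"
            if not path.exists():
                continue
            raw = cio.read_caller_vcf(path, caller)
            normalized = []
            for call in raw:
                span = ref_genome.slice(call.variant.chrom, call.variant.pos, call.variant.end)
                if "N" in span:
                    n_rejected_n += 1
                    continue
                v = normalize(call.variant, ref_genome)
                normalized.append(
                    call.__class__(
                        v, call.caller, call.tumor_alt_reads, call.tumor_depth,
                        call.germline_alt_reads, call.germline_depth,
                    )
                )
            callsets[caller] = normalized
        pairs.append(
            SamplePair(
                tumor_id=row.tumor_id,
                germline_id=row.germline_id,
                histology=row.histology,
                callsets=callsets,
                territory_mb=float(row.territory_mb),
            )
        )

    panel_keys = {}
    panel_dir = cohort_dir / "panel"
    if panel_dir.is_dir():
        for path in sorted(panel_dir.glob("*.vcf")):
            keys = set()
            for call in cio.read_caller_vcf(path):
                keys.add(variant_key(normalize(call.variant, ref_genome)))
            panel_keys[path.stem] = keys

    truth = None
    truth_path = cohort_dir / "truth.tsv"
    if truth_path.exists():
        truth = defaultdict(list)
        tdf = pd.read_csv(truth_path, sep="\t", dtype={"chrom": str})
        for r in tdf.itertuples(index=False):
            truth[r.tumor_id].append(
                TruthVariant(
                    variant=Variant(r.chrom, int(r.pos), r.ref, r.alt),
                    origin=r.origin,
                    true_tumor_vaf=float(r.true_tumor_vaf),
                    true_germline_vaf=float(r.true_germline_vaf),
                    in_coding=bool(r.in_coding),
                    pop_maf=float(r.pop_maf),
                )
            )
        truth = dict(truth)

    return {
        "ref_genome": ref_genome,
        "genes": genes,
        "pairs": pairs,
        "panel_keys": panel_keys,
        "pop_freq": pop_freq,
        "external_counts": external_counts,
        "truth": truth,
        "n_rejected_n": n_rejected_n,
    }


def run_pipeline(
    cohort_dir: str | Path,
    outdir: str | Path,
    filter_cfg: FilterConfig | None = None,
    sim_cfg: SimConfig | None = None,
) -> dict:
    """Run every stage and write the full report bundle to ``outdir``.

    If ``sim_cfg`` is given, the cohort is simulated into ``cohort_dir``
    first.  Returns a summary dict (also serialized in the outputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    filter_cfg = filter_cfg or FilterConfig()

    if sim_cfg is not None:
        log.info("stage simulate: seed=%d", sim_cfg.seed)
        _stage("simulate", lambda: write_cohort(simulate_cohort(sim_cfg), cohort_dir))

    data = _stage("load", lambda: load_cohort_dir(cohort_dir))
    ref_genome, genes = data["ref_genome"], data["genes"]

    # --- consolidate
    log.info("stage consolidate: %d pairs", len(data["pairs"]))
    decisions_by_pair = {}

    def _consolidate():
        for pair in data["pairs"]:
            cohort_counts = cohort_panel_counts(data["panel_keys"], exclude_germline=pair.germline_id)
            decisions_by_pair[pair.tumor_id] = consolidate(
                pair, cohort_counts, data["external_counts"], data["pop_freq"],
                genes, ref_genome, filter_cfg,
            )

    _stage("consolidate", _consolidate)

    audit_rows = []
    for tumor_id in sorted(decisions_by_pair):
        for d in decisions_by_pair[tumor_id]:
            v = d.variant
            audit_rows.append(
                {
                    "tumor_id": tumor_id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                    "alt": v.alt, "vclass": v.vclass,
                    "callers": ",".join(sorted(d.supporting_callers)),
                    "decision": "retained" if d.retained else "rejected",
                    "failed_rules": ",".join(d.failed_rules),
                    "gene_id": d.gene_id or "", "consequence": d.consequence,
                }
            )
    pd.DataFrame(audit_rows).to_csv(outdir / "decisions.tsv", sep="\t", index=False)

    # --- annotate retained variants
    cons_rows = []

    def _annotate():
        for tumor_id in sorted(decisions_by_pair):
            retained = [d.variant for d in decisions_by_pair[tumor_id] if d.retained]
            for call in annotate_variants(retained, genes, ref_genome):
                v = call.variant
                cons_rows.append(
                    {
                        "tumor_id": tumor_id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                        "alt": v.alt, "vclass": v.vclass, "gene_id": call.gene_id or "",
                        "consequence": call.consequence,
                        "protein_altering": int(call.protein_altering),
                    }
                )

    _stage("annotate", _annotate)
    cons_df = pd.DataFrame(
        cons_rows,
        columns=["tumor_id", "chrom", "pos", "ref", "alt", "vclass", "gene_id",
                 "consequence", "protein_altering"],
    )
    cons_df.to_csv(outdir / "consequences.tsv", sep="\t", index=False)

    # --- spectrum & burden
    pair_meta = {p.tumor_id: p for p in data["pairs"]}
    spectrum_rows, context_rows, burden_records = [], [], []
    cohort_variants = []

    def _spectrum():
        for tumor_id in sorted(decisions_by_pair):
            retained = [d.variant for d in decisions_by_pair[tumor_id] if d.retained]
            cohort_variants.extend(retained)
            profile = spectrum_profile(retained, ref_genome)
            frac = npcpg_fraction(profile)
            row = {"tumor_id": tumor_id, **profile.six_class_counts,
                   "n_substitutions": profile.n_substitutions,
                   "ct_at_cpg": profile.ct_at_cpg,
                   "npcpg_of_ct": "" if frac["of_ct"] is None else round(frac["of_ct"], 4)}
            spectrum_rows.append(row)
            context_rows.append({"tumor_id": tumor_id, **profile.context_counts})
            pair = pair_meta[tumor_id]
            burden_records.append(
                burden(tumor_id, pair.histology, retained, pair.territory_mb)
            )

    _stage("spectrum", _spectrum)
    pd.DataFrame(spectrum_rows).to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
    pd.DataFrame(context_rows, columns=["tumor_id", *CONTEXT_CLASSES]).to_csv(
        outdir / "contexts.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"sample_id": r.sample_id, "histology": r.histology,
             "n_coding_mutations": r.n_coding_mutations, "territory_mb": r.territory_mb,
             "mutations_per_mb": round(r.mutations_per_mb, 4),
             "hypermutated": int(r.hypermutated)}
            for r in burden_records
        ]
    ).to_csv(outdir / "burden.tsv", sep="\t", index=False)

    # --- cohort stats
    stats_out = {}

    def _stats():
        metadata = {p.tumor_id: p.histology for p in data["pairs"]}
        mutated = defaultdict(set)
        for row in cons_rows:
            if row["protein_altering"] and row["gene_id"]:
                mutated[row["gene_id"]].add(row["tumor_id"])
        recurrence = recurrence_table(
            {g: sorted(s) for g, s in mutated.items()}, {}, {}, metadata
        )
        recurrence.sort(key=lambda r: (-r.mutated_total, r.gene_id))
        rec_rows = []
        for r in recurrence:
            rec_rows.append(
                {
                    "gene_id": r.gene_id,
                    "mutated_discovery": r.mutated_samples_discovery,
                    "mutated_validation": r.mutated_samples_validation,
                    "denominator": r.denominator,
                    "frequency_percent": r.frequency_percent,
                    **{f"{h}_mutated": m for h, (m, _t) in r.per_histology.items()},
                }
            )
        pd.DataFrame(rec_rows).to_csv(outdir / "recurrence.tsv", sep="\t", index=False)
        stats_out["recurrence_top"] = rec_rows[:10]

        groups = group_burden(burden_records)
        stats_out["group_burden"] = {
            g: {**{k: v for k, v in d.items() if k != "range"}, "range": list(d["range"])}
            for g, d in groups.items()
        }
        by_group = defaultdict(list)
        for r in burden_records:
            by_group[r.histology].append(r.mutations_per_mb)
        tests = {}
        names = sorted(by_group)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = rank_sum(by_group[a], by_group[b])
                tests[f"burden_{a}_vs_{b}"] = {"test": res.test, "statistic": res.statistic,
                                               "p_value": res.p_value}
        # association of the top recurrent gene with histology
        if rec_rows:
            top = rec_rows[0]["gene_id"]
            table = []
            for h in names:
                mut = sum(1 for s in mutated[top] if metadata[s] == h)
                tot = sum(1 for s in metadata if metadata[s] == h)
                table.append([mut, tot - mut])
            try:
                res = chi_square(table)
                tests[f"{top}_histology_chi_square"] = {
                    "test": res.test, "statistic": res.statistic, "p_value": res.p_value
                }
            except ValueError:
                pass
            if len(names) >= 2:
                a, b = names[0], names[-1]
                t2 = [table[0], table[-1]]
                res = fisher_exact_2x2(t2)
                tests[f"{top}_{a}_vs_{b}_fisher"] = {
                    "test": res.test, "statistic": res.statistic, "p_value": res.p_value
                }
        stats_out["tests"] = tests

    _stage("stats", _stats)

    # --- evaluation against truth (when available)
    evaluation = None
    if data["truth"] is not None:
        all_decisions = [d for ds in decisions_by_pair.values() for d in ds]

        def _per_pair_eval():
            per = {}
            for tumor_id, ds in sorted(decisions_by_pair.items()):
                per[tumor_id] = evaluate_against_truth(ds, data["truth"].get(tumor_id, []))
            pooled = _pool_evaluation(decisions_by_pair, data["truth"])
            return {"per_pair": per, "pooled": pooled}

        evaluation = _stage("evaluate", _per_pair_eval)
        del all_decisions

    # --- funnel & summary
    funnel_total = defaultdict(int)
    for ds in decisions_by_pair.values():
        for k, v in filter_funnel(ds).items():
            funnel_total[k] += v
    summary = {
        "n_pairs": len(data["pairs"]),
        "funnel": dict(funnel_total),
        "stats": stats_out,
        "evaluation": evaluation,
        "n_rejected_overlapping_N": data["n_rejected_n"],
    }
    with open(outdir / "stats.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    report = render_report(outdir)
    (outdir / "report.md").write_text(report)
    _write_manifest(outdir, filter_cfg, sim_cfg)
    return summary


def _pool_evaluation(decisions_by_pair, truth_by_pair) -> dict:
    """Cohort-pooled sensitivity/precision (per-pair events pooled)."""
    tp = fn = fp = 0
    tp_c = {"snv": 0, "indel": 0}
    denom_c = {"snv": 0, "indel": 0}
    for tumor_id, ds in decisions_by_pair.items():
        truth = truth_by_pair.get(tumor_id, [])
        truth_keys = {variant_key(t.variant) for t in truth if t.origin == "somatic" and t.in_coding}
        retained = {variant_key(d.variant) for d in ds if d.retained}
        for t in truth:
            if t.origin != "somatic" or not t.in_coding:
                continue
            denom_c[t.variant.vclass] += 1
            if variant_key(t.variant) in retained:
                tp += 1
                tp_c[t.variant.vclass] += 1
            else:
                fn += 1
        fp += len(retained - truth_keys)
    n_truth = tp + fn
    n_ret = tp + fp
    return {
        "sensitivity": tp / n_truth if n_truth else None,
        "precision": tp / n_ret if n_ret else None,
        "sensitivity_snv": tp_c["snv"] / denom_c["snv"] if denom_c["snv"] else None,
        "sensitivity_indel": tp_c["indel"] / denom_c["indel"] if denom_c["indel"] else None,
        "n_truth": n_truth,
        "n_retained": n_ret,
    }


def render_report(outdir: str | Path) -> str:
    """Render the markdown landscape report from the written tables."""
    outdir = Path(outdir)
    with open(outdir / "stats.json") as fh:
        summary = json.load(fh)
    spectrum = pd.read_csv(outdir / "spectrum.tsv", sep="\t")

    lines = ["# Somatic mutation landscape", ""]
    lines.append("## Filter funnel")
    lines.append("")
    from consomatic.filtering import RULE_ORDER

    funnel = summary["funnel"]
    lines.append("| stage | candidates remaining |")
    lines.append("|---|---|")
    for key in ["candidates", *(f"after_{r}" for r in RULE_ORDER), "retained"]:
        if key in funnel:
            lines.append(f"| {key} | {funnel[key]} |")
    lines.append("")

    lines.append("## Mutation burden by histology")
    lines.append("")
    lines.append("| group | n | mean mutations | range | mutations/Mb | hypermutated |")
    lines.append("|---|---|---|---|---|---|")
    for g, d in sorted(summary["stats"].get("group_burden", {}).items()):
        lines.append(
            f"| {g} | {d['n_samples']} | {d['mean_mutations']:.1f} | "
            f"{d['range'][0]}-{d['range'][1]} | {d['mutations_per_mb']:.2f} | {d['n_hypermutated']} |"
        )
    lines.append("")

    lines.append("## Substitution spectrum (cohort)")
    lines.append("")
    totals = {c: int(spectrum[c].sum()) for c in SIX_CLASSES}
    n_sub = sum(totals.values())
    ct_cpg = int(spectrum["ct_at_cpg"].sum())
    lines.append("| class | count | fraction |")
    lines.append("|---|---|---|")
    for c in SIX_CLASSES:
        frac = totals[c] / n_sub if n_sub else 0.0
        lines.append(f"| {c} | {totals[c]} | {frac:.3f} |")
    if totals["C>T"]:
        lines.append("")
        lines.append(
            f"NpCpG fraction of C>T substitutions: {ct_cpg / totals['C>T']:.3f} "
            f"({ct_cpg}/{totals['C>T']})"
        )
    lines.append("")

    lines.append("## Most recurrently mutated genes")
    lines.append("")
    lines.append("| gene | mutated samples | frequency % |")
    lines.append("|---|---|---|")
    for r in summary["stats"].get("recurrence_top", []):
        lines.append(
            f"| {r['gene_id']} | {r['mutated_discovery'] + r['mutated_validation']}"
            f"/{r['denominator']} | {r['frequency_percent']} |"
        )
    lines.append("")

    if summary.get("evaluation"):
        pooled = summary["evaluation"]["pooled"]
        lines.append("## Evaluation against simulated truth")
        lines.append("")
        sens = pooled["sensitivity"]
        prec = pooled["precision"]
        lines.append(
            f"Sensitivity {100 * sens:.1f} % ({pooled['n_truth']} true coding somatic events), "
            f"precision {100 * prec:.1f} % ({pooled['n_retained']} retained)."
            if sens is not None and prec is not None
            else "No truth events to evaluate."
        )
        lines.append("")
    return "\n".join(lines)


def _stage(name: str, fn):
    try:
        return fn()
    except Exception as exc:  # noqa: BLE001 - stage attribution for the CLI
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def _write_manifest(outdir: Path, filter_cfg: FilterConfig, sim_cfg: SimConfig | None) -> None:
    import consomatic

    cfg_repr = json.dumps(
        {
            "filter": dataclasses_asdict(filter_cfg),
            "sim": dataclasses_asdict(sim_cfg) if sim_cfg else None,
        },
        sort_keys=True,
        default=sorted,
    )
    files = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        files[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = {
        "package_version": consomatic.__version__,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "seed": sim_cfg.seed if sim_cfg else None,
        "outputs_sha256": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def dataclasses_asdict(obj):
    import dataclasses as dc

    d = dc.asdict(obj)
    return {k: (sorted(v) if isinstance(v, frozenset) else dict(v) if isinstance(v, dict) else v)
            for k, v in d.items()}
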