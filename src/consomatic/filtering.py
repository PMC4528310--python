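"""Somatic variant consolidation: the multi-caller consensus filter cascade.

A candidate variant (grouped across callers by normalized key) is retained
only if it passes every rule:

1. ``support`` — SNVs called by >=2 of the five SNV-eligible callers;
   indels called by any of the four indel-eligible callers.
2. ``evidence`` — present in >=10 tumor reads (pindel) or >=2 tumor reads
   (any other caller); satisfied if any one call meets its threshold.
3. ``germline_vaf`` — mutant allele fraction <=5 % in the matched germline,
   evaluated on the maximum germline VAF across reporting callers.
4. ``vaf_gap`` — for indels reported by the tumor/germline-separate callers
   (pindel, unifiedgenotyper): tumor VAF at least 10 percentage points above
   germline VAF on at least one such call.
5. ``cohort_panel`` / ``external_panel`` — seen in at most two other
   germlines from the cohort, and at most two of the external germline
   exome panel.
6. ``pop_freq`` — population minor allele frequency <=5 % (novel = 0).
7. ``noncoding`` — only variants overlapping coding sequence or splice
   sites (+-2 bp intronic) are kept for the landscape analysis; applied
   last so biological-context rejections are audited separately.

Every input variant appears exactly once in the output with the full list
of rules it failed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from consomatic.consequence import annotate
from consomatic.variants import (
    CallerCall,
    GeneModel,
    GERMLINE_SEPARATE_CALLERS,
    INDEL_CALLERS,
    ReferenceGenome,
    SNV_CALLERS,
    SamplePair,
    variant_key,
)

RULE_ORDER = (
    "support",
    "evidence",
    "germline_vaf",
    "vaf_gap",
    "cohort_panel",
    "external_panel",
    "pop_freq",
    "noncoding",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the consolidation cascade (defaults per the study design)."""

    min_snv_callers: int = 2
    snv_caller_set: frozenset = SNV_CALLERS
    indel_caller_set: frozenset = INDEL_CALLERS
    min_tumor_reads_pindel: int = 10
    min_tumor_reads_other: int = 2
    max_germline_vaf: float = 0.05
    min_tumor_germline_vaf_gap: float = 0.10
    max_panel_cohort: int = 2
    max_panel_external: int = 2
    panel_external_size: int = 147
    max_pop_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_snv_callers", "min_tumor_reads_pindel", "min_tumor_reads_other",
                     "max_panel_cohort", "max_panel_external", "panel_external_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("max_germline_vaf", "min_tumor_germline_vaf_gap", "max_pop_maf"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class FilterDecision:
    """Retained/rejected verdict with the audit trail of failed rules."""

    variant: object
    retained: bool
    supporting_callers: set[str]
    failed_rules: list[str] = field(default_factory=list)
    low_confidence: bool = False
    gene_id: str | None = None
    consequence: str | None = None


class MixedKeyError(ValueError):
    """Calls passed to a per-variant rule do not share one variant key."""


def _check_single_key(calls: Sequence[CallerCall]):
    keys = {variant_key(c.variant) for c in calls}
    if len(keys) != 1:
        raise MixedKeyError(f"expected one variant key, got {sorted(keys)}")
    return keys.pop()


def support_rule(calls: Sequence[CallerCall], cfg: FilterConfig) -> tuple[bool, set[str]]:
    """Consensus support: >=2 eligible callers for SNVs, any one for indels.

    Callers outside the class-eligible set are ignored for counting.
    Returns (passed, supporting caller set).
    """
    _check_single_key(calls)
    vclass = calls[0].variant.vclass
    emitted = {c.caller for c in calls}
    if vclass == "snv":
        supporting = emitted & cfg.snv_caller_set
        return len(supporting) >= cfg.min_snv_callers, supporting
    supporting = emitted & cfg.indel_caller_set
    return len(supporting) >= 1, supporting


def evidence_rule(call: CallerCall, cfg: FilterConfig) -> bool:
    """Tumor read support for one call: >=10 reads for pindel, >=2 otherwise."""
    threshold = cfg.min_tumor_reads_pindel if call.caller == "pindel" else cfg.min_tumor_reads_other
    return call.tumor_alt_reads >= threshold


def germline_vaf_rule(call: CallerCall, cfg: FilterConfig) -> bool:
    """Germline contamination check: mutant fraction <=5 % in matched germline.

    Zero germline depth counts as 0 % (pass); the cascade flags it
    low-confidence.
    """
    return call.germline_vaf <= cfg.max_germline_vaf


def vaf_gap_rule(call: CallerCall, cfg: FilterConfig) -> bool:
    """Tumor-vs-germline fraction gap for pindel/unifiedgenotyper indels.

    Vacuously passes for SNVs and for calls from jointly-genotyping somatic
    callers, which already condition on the matched germline.
    """
    if call.variant.vclass != "indel" or call.caller not in GERMLINE_SEPARATE_CALLERS:
        return True
    return call.tumor_vaf - call.germline_vaf >= cfg.min_tumor_germline_vaf_gap


def panel_rules(
    key: tuple,
    cohort_counts: Mapping[tuple, int],
    external_counts: Mapping[tuple, int],
    cfg: FilterConfig,
) -> tuple[bool, bool]:
    """Panel-of-normals checks; a variant absent from a panel counts 0.

    ``cohort_counts`` must already exclude the pair's own matched germline.
    """
    cohort_ok = cohort_counts.get(key, 0) <= cfg.max_panel_cohort
    external_ok = external_counts.get(key, 0) <= cfg.max_panel_external
    return cohort_ok, external_ok


def pop_freq_rule(key: tuple, pop_freq: Mapping[tuple, float], cfg: FilterConfig) -> bool:
    """Population-frequency check, inclusive at the threshold; novel passes."""
    return pop_freq.get(key, 0.0) <= cfg.max_pop_maf


def consolidate(
    pair: SamplePair,
    cohort_panel_counts: Mapping[tuple, int],
    external_panel_counts: Mapping[tuple, int],
    pop_freq: Mapping[tuple, float],
    genes: Sequence[GeneModel],
    ref_genome: ReferenceGenome,
    cfg: FilterConfig | None = None,
) -> list[FilterDecision]:
    """Run the full cascade for one tumor/germline pair.

    Callsets must hold normalized variants.  Output is ordered by variant
    key and contains every distinct input variant exactly once; a decision's
    ``failed_rules`` lists all rules it failed, in cascade order.
    """
    cfg = cfg or FilterConfig()
    groups: dict[tuple, list[CallerCall]] = {}
    for call in pair.all_calls():
        groups.setdefault(variant_key(call.variant), []).append(call)

    keys = sorted(groups)
    variants = [groups[k][0].variant for k in keys]
    consequences = annotate(variants, genes, ref_genome)

    decisions = []
    for key, variant, cons in zip(keys, variants, consequences):
        calls = groups[key]
        failed: list[str] = []
        passed_support, supporting = support_rule(calls, cfg)
        if not passed_support:
            failed.append("support")
        if not any(evidence_rule(c, cfg) for c in calls):
            failed.append("evidence")
        germ_calls = [c for c in calls if c.germline_depth > 0]
        low_conf = len(germ_calls) < len(calls)
        max_germ_vaf = max((c.germline_vaf for c in germ_calls), default=0.0)
        if max_germ_vaf > cfg.max_germline_vaf:
            failed.append("germline_vaf")
        gap_calls = [
            c for c in calls
            if c.variant.vclass == "indel" and c.caller in GERMLINE_SEPARATE_CALLERS
        ]
        if gap_calls and not any(vaf_gap_rule(c, cfg) for c in gap_calls):
            failed.append("vaf_gap")
        cohort_ok, external_ok = panel_rules(key, cohort_panel_counts, external_panel_counts, cfg)
        if not cohort_ok:
            failed.append("cohort_panel")
        if not external_ok:
            failed.append("external_panel")
        if not pop_freq_rule(key, pop_freq, cfg):
            failed.append("pop_freq")
        if cons.consequence == "noncoding":
            failed.append("noncoding")
        decisions.append(
            FilterDecision(
                variant=variant,
                retained=not failed,
                supporting_callers=supporting,
                failed_rules=failed,
                low_confidence=low_conf,
                gene_id=cons.gene_id,
                consequence=cons.consequence,
            )
        )
    return decisions


def cohort_panel_counts(
    panel_keys: Mapping[str, Iterable[tuple]],
    exclude_germline: str | None = None,
) -> dict[tuple, int]:
    """Per-variant carrier counts over the cohort's *other* germline samples."""
    counts: dict[tuple, int] = {}
    for germline_id, keys in panel_keys.items():
        if germline_id == exclude_germline:
            continue
        for key in set(keys):
            counts[key] = counts.get(key, 0) + 1
    return counts


def filter_funnel(decisions: Sequence[FilterDecision]) -> dict[str, int]:
    """Candidate counts surviving each successive rule (first-failure funnel)."""
    funnel = {"candidates": len(decisions)}
    remaining = len(decisions)
    for rule in RULE_ORDER:
        remaining -= sum(1 for d in decisions if d.failed_rules and d.failed_rules[0] == rule)
        funnel[f"after_{rule}"] = remaining
    funnel["retained"] = sum(1 for d in decisions if d.retained)
    return funnel


def evaluate_against_truth(decisions: Sequence[FilterDecision], truth_variants) -> dict:
    """Sensitivity/precision of the consolidated call set against known truth.

    Sensitivity is over true *coding* somatic variants (the cascade's target
    population); precision is the fraction of retained variants that are
    true somatic events.  Both are reported overall and per variant class.
    """
    from consomatic.variants import variant_key as vkey

    truth_somatic = {
        vkey(t.variant): t for t in truth_variants if t.origin == "somatic" and t.in_coding
    }
    retained = {vkey(d.variant) for d in decisions if d.retained}

    def _stats(vclass: str | None) -> dict:
        denom = [k for k, t in truth_somatic.items() if vclass in (None, t.variant.vclass)]
        tp = sum(1 for k in denom if k in retained)
        ret = [k for k in retained if vclass in (None, k and _key_vclass(k))]
        ret_tp = sum(1 for k in ret if k in truth_somatic)
        return {
            "sensitivity": tp / len(denom) if denom else None,
            "precision": ret_tp / len(ret) if ret else None,
            "n_truth": len(denom),
            "n_retained": len(ret),
            "n_true_positive": tp,
        }

    def _key_vclass(key: tuple) -> str:
        _, _, ref, alt = key
        return "snv" if len(ref) == 1 and len(alt) == 1 else "indel"

    return {"overall": _stats(None), "snv": _stats("snv"), "indel": _stats("indel")}
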