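"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles (enumeration,
rational arithmetic, explicit rule-by-rule checks) without calling the
package code paths they validate.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.stats import hypergeom


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Fixes all margins of [[a, b], [c, d]] and sums P(table) over every table
    whose probability does not exceed the observed one (with a tiny relative
    tolerance against floating-point ties, the standard convention).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def mannwhitney_exact_enumeration(xs, ys) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    from itertools import combinations

    pooled = list(xs) + list(ys)
    n_x = len(xs)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}  # no ties assumed

    def u_stat(group):
        r = sum(ranks[v] for v in group)
        return r - n_x * (n_x + 1) / 2

    u_obs = u_stat(list(xs))
    n_total = 0
    n_extreme = 0
    mean_u = n_x * len(ys) / 2
    for combo in combinations(range(len(pooled)), n_x):
        u = u_stat([pooled[i] for i in combo])
        n_total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            n_extreme += 1
    return n_extreme / n_total


def percent_rational(k: int, n: int, ndigits: int = 1) -> float:
    """Half-up percentage via exact rational arithmetic."""
    x = Fraction(100 * k, n) * 10**ndigits
    q, r = divmod(x.numerator, x.denominator)
    if 2 * r >= x.denominator:
        q += 1
    return q / 10**ndigits


def cascade_brute_force(
    calls_by_key: dict,
    cohort_counts: dict,
    external_counts: dict,
    pop_freq: dict,
    coding_keys: set,
    *,
    snv_callers=frozenset({"mutect", "jointsnvmix", "somaticsniper", "varscan", "unifiedgenotyper"}),
    indel_callers=frozenset({"somaticindeldetector", "varscan", "pindel", "unifiedgenotyper"}),
) -> dict:
    """Literal rule-by-rule evaluation of the consolidation cascade.

    ``calls_by_key`` maps a variant key to its CallerCall list;
    ``coding_keys`` is the externally known set of keys overlapping coding
    sequence or splice sites.  Returns key -> set of failed rule names.
    """
    out = {}
    for key, calls in calls_by_key.items():
        chrom, pos, ref, alt = key
        is_snv = len(ref) == 1 and len(alt) == 1
        failed = set()

        emitted = {c.caller for c in calls}
        if is_snv:
            if len(emitted & snv_callers) < 2:
                failed.add("support")
        else:
            if len(emitted & indel_callers) < 1:
                failed.add("support")

        ok = False
        for c in calls:
            need = 10 if c.caller == "pindel" else 2
            if c.tumor_alt_reads >= need:
                ok = True
        if not ok:
            failed.add("evidence")

        worst = 0.0
        for c in calls:
            if c.germline_depth > 0:
                worst = max(worst, c.germline_alt_reads / c.germline_depth)
        if worst > 0.05:
            failed.add("germline_vaf")

        gap_calls = [
            c for c in calls
            if not is_snv and c.caller in ("pindel", "unifiedgenotyper")
        ]
        if gap_calls:
            best_gap = max(
                (c.tumor_alt_reads / c.tumor_depth if c.tumor_depth else 0.0)
                - (c.germline_alt_reads / c.germline_depth if c.germline_depth else 0.0)
                for c in gap_calls
            )
            if best_gap < 0.10:
                failed.add("vaf_gap")

        if cohort_counts.get(key, 0) > 2:
            failed.add("cohort_panel")
        if external_counts.get(key, 0) > 2:
            failed.add("external_panel")
        if pop_freq.get(key, 0.0) > 0.05:
            failed.add("pop_freq")
        if key not in coding_keys:
            failed.add("noncoding")
        out[key] = failed
    return out
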