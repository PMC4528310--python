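"""Cohort-level recurrence tabulation and group-comparison statistics.

Gene recurrence merges a discovery (exome) cohort with gene-specific
validation screens, so denominators legitimately differ between genes.
Group comparisons use Fisher's exact test (2x2), the Pearson chi-square
test (r x c, uncorrected by default), and the two-sided Mann-Whitney U
rank-sum test for burden comparisons between small skewed groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from consomatic.util import percent


@dataclass(frozen=True)
class GeneRecurrence:
    gene_id: str
    mutated_samples_discovery: int
    mutated_samples_validation: int
    denominator: int
    per_histology: dict = field(default_factory=dict, compare=False)

    @property
    def mutated_total(self) -> int:
        return self.mutated_samples_discovery + self.mutated_samples_validation

    @property
    def frequency_percent(self) -> float:
        return percent(self.mutated_total, self.denominator)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple
    test: str
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def combined_frequency(mut_discovery: int, mut_validation: int, denominator: int) -> tuple:
    """Merged discovery+validation mutation frequency.

    Returns ``(fraction, percent)`` with the percent rounded half-up to one
    decimal, the convention of printed cohort tables.
    """
    if denominator == 0:
        raise ValueError("zero denominator")
    total = mut_discovery + mut_validation
    if total > denominator:
        raise ValueError("mutated samples exceed cohort size")
    return total / denominator, percent(total, denominator)


def detection_rate(detected_by_class: Mapping[str, tuple[int, int]]) -> dict:
    """Per-class and overall detection (or confirmation) percentages.

    ``detected_by_class`` maps a class name to ``(detected, total)``; the
    overall rate pools numerators and denominators before rounding.
    """
    totals = [t for _, t in detected_by_class.values()]
    if sum(totals) == 0:
        raise ValueError("no assessed variants")
    out = {}
    for cls, (detected, total) in detected_by_class.items():
        if detected > total:
            raise ValueError(f"{cls}: detected > total")
        out[cls] = percent(detected, total) if total else None
    out["overall"] = percent(
        sum(d for d, _ in detected_by_class.values()), sum(totals)
    )
    return out


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return arr


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities, over all tables with
    the observed margins, that do not exceed the observed table's
    probability (probability-mass ordering).
    """
    arr = _as_table(table)
    if arr.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    res = sps.fisher_exact(arr, alternative="two-sided")
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        test="fisher_exact",
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
    )


def chi_square(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c table.

    Uncorrected by default; ``yates=True`` applies the continuity
    correction (2x2 only, as in scipy).
    """
    arr = _as_table(table)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    stat, p, _dof, _exp = sps.chi2_contingency(arr, correction=yates)
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        test="chi_square",
        statistic=float(stat),
        p_value=min(float(p), 1.0),
    )


def rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> ContingencyResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration for samples of at most 8 per group without ties;
    normal approximation with tie correction otherwise.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ContingencyResult(
        table=(tuple(a.tolist()), tuple(b.tolist())),
        test="rank_sum",
        statistic=float(res.statistic),
        p_value=min(float(res.pvalue), 1.0),
    )


def recurrence_table(
    discovery_mutated: Mapping[str, Sequence[str]],
    validation_mutated: Mapping[str, Sequence[str]],
    validation_denominators: Mapping[str, int],
    metadata: Mapping[str, str],
    discovery_size: int | None = None,
) -> list[GeneRecurrence]:
    """Per-gene mutated-sample counts merged across discovery and validation.

    ``discovery_mutated`` / ``validation_mutated`` map gene -> sample ids
    carrying at least one mutation (a sample counts once however many
    mutations it has).  ``metadata`` maps sample id -> histology group and
    must cover every sample mentioned.  Each gene's denominator is the
    discovery cohort size plus that gene's validation screen size.
    """
    if discovery_size is None:
        discovery_size = len(metadata)
    out = []
    for gene in sorted(set(discovery_mutated) | set(validation_mutated)):
        disc = set(discovery_mutated.get(gene, ()))
        val = set(validation_mutated.get(gene, ()))
        for sample in disc | val:
            if sample not in metadata:
                raise KeyError(f"sample {sample!r} missing from metadata")
        per_hist: dict[str, tuple[int, int]] = {}
        for hist in sorted(set(metadata.values())):
            mutated = sum(1 for s in disc | val if metadata[s] == hist)
            tested = sum(1 for s in metadata if metadata[s] == hist)
            per_hist[hist] = (mutated, tested)
        out.append(
            GeneRecurrence(
                gene_id=gene,
                mutated_samples_discovery=len(disc),
                mutated_samples_validation=len(val - disc),
                denominator=discovery_size + validation_denominators.get(gene, 0),
                per_histology=per_hist,
            )
        )
    return out
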