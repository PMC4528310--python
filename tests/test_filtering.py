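"""Consensus filter cascade: rule boundaries, oracle equivalence, audit."""

import numpy as np
import pytest

from oracles import cascade_brute_force

from consomatic.filtering import (
    FilterConfig,
    MixedKeyError,
    cohort_panel_counts,
    consolidate,
    evaluate_against_truth,
    evidence_rule,
    filter_funnel,
    germline_vaf_rule,
    panel_rules,
    pop_freq_rule,
    support_rule,
    vaf_gap_rule,
)
from consomatic.simulate import TruthVariant
from consomatic.variants import CallerCall, GeneModel, ReferenceGenome, SamplePair, Variant

CFG = FilterConfig()


def call(caller, variant=None, t_alt=30, t_dp=100, g_alt=0, g_dp=100):
    variant = variant or Variant("chr1", 10, "A", "T")
    return CallerCall(variant, caller, t_alt, t_dp, g_alt, g_dp)


class TestSupportRule:
    def test_snv_two_eligible_callers_pass(self):
        passed, supp = support_rule([call("mutect"), call("varscan")], CFG)
        assert passed and supp == {"mutect", "varscan"}

    def test_snv_single_caller_fails(self):
        passed, _ = support_rule([call("mutect")], CFG)
        assert not passed

    def test_snv_ineligible_callers_ignored(self):
        # pindel/somaticindeldetector cannot support an SNV
        passed, supp = support_rule([call("mutect"), call("pindel"), call("somaticindeldetector")], CFG)
        assert not passed and supp == {"mutect"}

    def test_indel_any_single_eligible_caller_passes(self):
        indel = Variant("chr1", 10, "AT", "A")
        passed, supp = support_rule([call("pindel", indel)], CFG)
        assert passed and supp == {"pindel"}

    def test_indel_snv_only_caller_cannot_support(self):
        indel = Variant("chr1", 10, "AT", "A")
        passed, _ = support_rule([call("mutect", indel)], CFG)
        assert not passed

    def test_mixed_keys_error(self):
        with pytest.raises(MixedKeyError):
            support_rule([call("mutect"), call("varscan", Variant("chr1", 11, "C", "G"))], CFG)


class TestEvidenceRule:
    @pytest.mark.parametrize(
        "caller,alt_reads,expected",
        [
            ("pindel", 9, False),
            ("pindel", 10, True),
            ("mutect", 1, False),
            ("mutect", 2, True),
            ("varscan", 2, True),
        ],
    )
    def test_boundaries(self, caller, alt_reads, expected):
        v = Variant("chr1", 10, "AT", "A") if caller == "pindel" else None
        assert evidence_rule(call(caller, v, t_alt=alt_reads), CFG) is expected


class TestGermlineVafRule:
    def test_four_percent_passes(self):
        assert germline_vaf_rule(call("mutect", g_alt=1, g_dp=25), CFG)

    def test_eight_percent_fails(self):
        assert not germline_vaf_rule(call("mutect", g_alt=2, g_dp=25), CFG)

    def test_boundary_inclusive(self):
        assert germline_vaf_rule(call("mutect", g_alt=5, g_dp=100), CFG)

    def test_zero_depth_passes(self):
        assert germline_vaf_rule(call("mutect", g_alt=0, g_dp=0), CFG)


class TestVafGapRule:
    INDEL = Variant("chr1", 10, "AT", "A")

    def test_five_point_gap_fails(self):
        c = call("pindel", self.INDEL, t_alt=30, t_dp=100, g_alt=25, g_dp=100)
        assert not vaf_gap_rule(c, CFG)

    def test_fifteen_point_gap_passes(self):
        c = call("pindel", self.INDEL, t_alt=40, t_dp=100, g_alt=25, g_dp=100)
        assert vaf_gap_rule(c, CFG)

    def test_snv_not_in_scope(self):
        c = call("unifiedgenotyper", t_alt=10, t_dp=100, g_alt=9, g_dp=100)
        assert vaf_gap_rule(c, CFG)

    def test_joint_caller_indel_not_in_scope(self):
        c = call("varscan", self.INDEL, t_alt=10, t_dp=100, g_alt=9, g_dp=100)
        assert vaf_gap_rule(c, CFG)


class TestPanelAndPopRules:
    KEY = ("chr1", 10, "A", "T")

    @pytest.mark.parametrize("count,expected", [(0, True), (2, True), (3, False)])
    def test_cohort_boundary(self, count, expected):
        cohort_ok, _ = panel_rules(self.KEY, {self.KEY: count}, {}, CFG)
        assert cohort_ok is expected

    def test_absent_counts_zero(self):
        assert panel_rules(self.KEY, {}, {}, CFG) == (True, True)

    @pytest.mark.parametrize("maf,expected", [(0.05, True), (0.051, False), (0.0, True)])
    def test_pop_freq_boundary(self, maf, expected):
        assert pop_freq_rule(self.KEY, {self.KEY: maf}, CFG) is expected

    def test_novel_variant_passes(self):
        assert pop_freq_rule(self.KEY, {}, CFG)


def _toy_world():
    """A 90 bp genome with one gene; returns (ref, gene, coding_keys fn)."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=90))
    ref = ReferenceGenome({"chr1": seq})
    gene = GeneModel("g1", "chr1", "+", ((10, 30), (41, 61)), 10, 61)  # CDS 42 bp
    coding = set(gene.cds_positions()) | gene.splice_positions()
    return ref, gene, coding


class TestConsolidate:
    def _build_candidates(self, ref, coding_positions, rng, n=40):
        """Random candidates straddling every rule boundary."""
        callers = ["mutect", "jointsnvmix", "somaticsniper", "varscan",
                   "somaticindeldetector", "pindel", "unifiedgenotyper"]
        seq = ref.contigs["chr1"]
        calls, cohort_counts, external_counts, pop_freq = [], {}, {}, {}
        positions = rng.choice(np.arange(5, 85), size=n, replace=False)
        for pos in positions:
            pos = int(pos)
            base = seq[pos - 1]
            if rng.random() < 0.4:  # indel (1-2 bp deletion)
                length = int(rng.integers(1, 3))
                v = Variant("chr1", pos, seq[pos - 1 : pos + length], base)
            else:
                v = Variant("chr1", pos, base, rng.choice([b for b in "ACGT" if b != base]))
            from consomatic.variants import normalize, variant_key

            v = normalize(v, ref)
            key = variant_key(v)
            n_callers = int(rng.integers(1, 5))
            for caller in rng.choice(callers, size=n_callers, replace=False):
                t_dp, g_dp = int(rng.integers(20, 120)), int(rng.integers(0, 120))
                t_alt = int(rng.integers(0, min(t_dp, 15) + 1))
                g_alt = int(rng.integers(0, min(g_dp, 12) + 1)) if g_dp else 0
                calls.append(CallerCall(v, str(caller), t_alt, t_dp, g_alt, g_dp))
            if rng.random() < 0.3:
                cohort_counts[key] = int(rng.integers(1, 5))
            if rng.random() < 0.3:
                external_counts[key] = int(rng.integers(1, 5))
            if rng.random() < 0.3:
                pop_freq[key] = float(rng.uniform(0, 0.12))
        return calls, cohort_counts, external_counts, pop_freq

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        ref, gene, coding = _toy_world()
        rng = np.random.default_rng(seed)
        calls, cohort_counts, external_counts, pop_freq = self._build_candidates(ref, coding, rng)
        pair = SamplePair("T1", "N1", "benign", {"mutect": calls}, 30.0)
        decisions = consolidate(pair, cohort_counts, external_counts, pop_freq, [gene], ref)

        from consomatic.variants import variant_key

        by_key = {}
        for c in calls:
            by_key.setdefault(variant_key(c.variant), []).append(c)
        # coding status from interval geometry, independent of the package's
        # annotation code: splice flanks count; a deletion counts via its
        # removed bases, an insertion or SNV via its (anchor) position
        cds = set(gene.cds_positions())
        splice = gene.splice_positions()
        coding_keys = set()
        for k in by_key:
            _, pos, kref, kalt = k
            covered = set(range(pos, pos + len(kref)))
            if covered & splice:
                coding_keys.add(k)
            elif len(kref) > 1:  # deletion: removed bases are pos+1..end
                removed = set(range(pos + 1, pos + len(kref)))
                if removed & cds:
                    coding_keys.add(k)
            elif pos in cds:  # SNV or insertion anchor
                coding_keys.add(k)
        expected = cascade_brute_force(by_key, cohort_counts, external_counts, pop_freq, coding_keys)
        assert len(decisions) == len(by_key)
        for d in decisions:
            key = variant_key(d.variant)
            assert set(d.failed_rules) == expected[key], (key, d.failed_rules, expected[key])
            assert d.retained == (not expected[key])

    def test_empty_callsets(self):
        ref, gene, _ = _toy_world()
        pair = SamplePair("T1", "N1", "benign", {}, 30.0)
        assert consolidate(pair, {}, {}, {}, [gene], ref) == []

    def test_relaxed_thresholds_retain_union_of_eligible(self):
        ref, gene, coding = _toy_world()
        cfg = FilterConfig(
            min_snv_callers=1, min_tumor_reads_pindel=0, min_tumor_reads_other=0,
            max_germline_vaf=1.0, min_tumor_germline_vaf_gap=0.0,
            max_panel_cohort=10**6, max_panel_external=10**6, max_pop_maf=1.0,
        )
        pos = sorted(coding)[0]
        base = ref.contigs["chr1"][pos - 1]
        alt = "T" if base != "T" else "C"
        v = Variant("chr1", pos, base, alt)
        pair = SamplePair("T1", "N1", "benign", {"mutect": [call("mutect", v, g_alt=50, g_dp=100)]}, 30.0)
        decisions = consolidate(pair, {}, {}, {}, [gene], ref, cfg)
        assert [d.retained for d in decisions] == [True]

    def test_order_independence(self):
        ref, gene, _ = _toy_world()
        rng = np.random.default_rng(9)
        calls, cc, ec, pf = self._build_candidates(ref, set(), rng, n=25)
        pair_fwd = SamplePair("T1", "N1", "benign", {"mutect": calls}, 30.0)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        pair_rev = SamplePair("T1", "N1", "benign", {"mutect": shuffled}, 30.0)
        d1 = consolidate(pair_fwd, cc, ec, pf, [gene], ref)
        d2 = consolidate(pair_rev, cc, ec, pf, [gene], ref)
        assert [(d.variant, d.retained, d.failed_rules) for d in d1] == [
            (d.variant, d.retained, d.failed_rules) for d in d2
        ]

    def test_tightening_thresholds_never_grows_retained(self):
        ref, gene, _ = _toy_world()
        rng = np.random.default_rng(13)
        calls, cc, ec, pf = self._build_candidates(ref, set(), rng, n=30)
        pair = SamplePair("T1", "N1", "benign", {"mutect": calls}, 30.0)
        base = {d.variant for d in consolidate(pair, cc, ec, pf, [gene], ref) if d.retained}
        tighter = [
            FilterConfig(min_snv_callers=3),
            FilterConfig(min_tumor_reads_other=5),
            FilterConfig(max_germline_vaf=0.01),
            FilterConfig(max_panel_cohort=0),
            FilterConfig(max_pop_maf=0.0),
            FilterConfig(min_tumor_germline_vaf_gap=0.3),
        ]
        for cfg in tighter:
            retained = {d.variant for d in consolidate(pair, cc, ec, pf, [gene], ref, cfg) if d.retained}
            assert retained <= base

    def test_audit_completeness_and_funnel_conservation(self):
        ref, gene, _ = _toy_world()
        rng = np.random.default_rng(21)
        calls, cc, ec, pf = self._build_candidates(ref, set(), rng, n=35)
        pair = SamplePair("T1", "N1", "benign", {"mutect": calls}, 30.0)
        decisions = consolidate(pair, cc, ec, pf, [gene], ref)
        for d in decisions:
            assert d.retained == (d.failed_rules == [])
        funnel = filter_funnel(decisions)
        assert funnel["after_noncoding"] == funnel["retained"]
        drops = funnel["candidates"] - funnel["retained"]
        assert drops == sum(1 for d in decisions if d.failed_rules)


class TestCohortPanelCounts:
    def test_excludes_own_germline(self):
        key = ("chr1", 10, "A", "T")
        panel = {"N1": [key], "N2": [key], "N3": [key, key]}
        assert cohort_panel_counts(panel, exclude_germline="N1") == {key: 2}
        assert cohort_panel_counts(panel)[key] == 3


class TestEvaluateAgainstTruth:
    def _truth(self, variants):
        return [
            TruthVariant(v, "somatic", 0.4, 0.0, True) for v in variants
        ]

    def test_perfect_pipeline(self):
        from consomatic.filtering import FilterDecision

        vs = [Variant("chr1", p, "A", "T") for p in (10, 20, 30)]
        decisions = [FilterDecision(v, True, {"mutect", "varscan"}) for v in vs]
        res = evaluate_against_truth(decisions, self._truth(vs))
        assert res["overall"]["sensitivity"] == 1.0
        assert res["overall"]["precision"] == 1.0

    def test_known_mutation_arithmetic(self):
        # 27/27 SNVs plus 4/5 indels recovered -> 31/32 = 96.9 %
        from consomatic.filtering import FilterDecision

        snvs = [Variant("chr1", p, "A", "T") for p in range(10, 37)]
        indels = [Variant("chr1", p, "AT", "A") for p in range(100, 110, 2)]
        truth = self._truth(snvs + indels)
        retained = snvs + indels[:4]
        decisions = [FilterDecision(v, True, {"varscan"}) for v in retained]
        res = evaluate_against_truth(decisions, truth)
        assert res["snv"]["sensitivity"] == 1.0
        assert res["indel"]["sensitivity"] == pytest.approx(0.8)
        assert res["overall"]["sensitivity"] == pytest.approx(31 / 32)
        assert round(100 * res["overall"]["sensitivity"], 1) == 96.9
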