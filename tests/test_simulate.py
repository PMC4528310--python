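"""Synthetic cohort generator: determinism, composition, caller emulation."""

import dataclasses

import numpy as np
import pytest

from consomatic.simulate import (
    CallerProfile,
    SimConfig,
    cds_territory_mb,
    default_caller_profiles,
    emulate_calls,
    expected_consensus_snv_sensitivity,
    generate_gene_models,
    generate_reference,
    simulate_truth,
)
from consomatic.spectrum import cpg_opportunity_fraction, spectrum_profile
from consomatic.variants import CALLERS, variant_key


def _cfg(**overrides):
    base = dict(
        seed=3, n_contigs=1, contig_length=120_000, n_genes=60,
        n_pairs={"benign": 1, "borderline": 1, "carcinoma": 1},
        germline_snp_rate=2e-4,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestGenerateReference:
    def test_gc_fraction_within_binomial_bound(self):
        cfg = SimConfig(seed=5, n_contigs=1, contig_length=1_000_000)
        ref = generate_reference(cfg)
        seq = ref.contigs["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        sigma = np.sqrt(cfg.gc_fraction * (1 - cfg.gc_fraction) / len(seq))
        assert abs(gc - cfg.gc_fraction) <= 3 * sigma

    def test_same_seed_identical(self):
        cfg = _cfg()
        assert generate_reference(cfg).contigs == generate_reference(cfg).contigs

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(contig_length=0)


class TestGeneModels:
    def test_construction_territory(self):
        cfg = _cfg(n_genes=10, exons_per_gene=3, exon_length=150)
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        assert len(genes) == 10
        # 3 x 150 = 450 bp CDS per gene, already divisible by 3
        for g in genes:
            assert len(g.cds_positions()) == 450
        assert cds_territory_mb(genes) == pytest.approx(4500 / 1e6)

    def test_infeasible_packing_rejected(self):
        cfg = _cfg(n_genes=500, contig_length=50_000)
        ref = generate_reference(cfg)
        with pytest.raises(ValueError, match="pack"):
            generate_gene_models(cfg, ref)

    def test_minus_strand_sees_reverse_complement(self):
        from consomatic.variants import _revcomp

        cfg = _cfg()
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        minus = next(g for g in genes if g.strand == "-")
        plus_reading = "".join(
            ref.slice(minus.chrom, s, e) for s, e in minus.cds_intervals()
        )
        assert minus.cds_sequence(ref) == _revcomp(plus_reading)


class TestSimulateTruth:
    def test_somatic_count_poisson_mean(self):
        # burden 1.0/Mb x territory 30 Mb, averaged over 50 pairs
        cfg = _cfg(
            n_pairs={"benign": 50},
            burden_per_mb_by_group={"benign": 1.0},
            territory_mb_by_group={"benign": 30.0},
            germline_snp_rate=0.0,
        )
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        counts = [
            sum(1 for t in pt.variants if t.origin == "somatic")
            for pt in truth.pairs.values()
        ]
        mean = np.mean(counts)
        sigma_mean = np.sqrt(30.0 / 50)
        assert abs(mean - 30.0) <= 3 * sigma_mean

    def test_unweighted_cpg_matches_opportunity(self):
        cfg = _cfg(
            cpg_ct_weight=1.0, indel_fraction=0.0,
            n_pairs={"carcinoma": 8},
            burden_per_mb_by_group={"carcinoma": 3.0},
            territory_mb_by_group={"carcinoma": 40.0},
            germline_snp_rate=0.0,
        )
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        snvs = [
            t.variant for pt in truth.pairs.values() for t in pt.variants
            if t.variant.vclass == "snv"
        ]
        profile = spectrum_profile(snvs, ref)
        n_ct = profile.six_class_counts["C>T"]
        observed = profile.ct_at_cpg / n_ct
        expected = cpg_opportunity_fraction(ref)
        sigma = np.sqrt(expected * (1 - expected) / n_ct)
        assert abs(observed - expected) <= 3 * sigma + 0.01

    def test_zero_indel_fraction(self):
        cfg = _cfg(indel_fraction=0.0, germline_indel_fraction=0.0)
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        for pt in truth.pairs.values():
            assert all(t.variant.vclass == "snv" for t in pt.variants)

    def test_somatic_germline_vaf_invariants(self):
        cfg = _cfg()
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        for pt in truth.pairs.values():
            for t in pt.variants:
                if t.origin == "somatic":
                    assert t.true_germline_vaf == 0.0 and t.in_coding
                else:
                    assert t.true_germline_vaf in (0.5, 1.0)


class TestEmulateCalls:
    def _perfect_profiles(self):
        profiles = {}
        for name, p in default_caller_profiles().items():
            profiles[name] = dataclasses.replace(
                p, sens_snv=1.0 if p.handles_snv else 0.0,
                sens_indel=1.0 if p.handles_indel else 0.0, fp_per_mb=0.0,
            )
        return profiles

    def test_perfect_sensitivity_no_fp(self):
        cfg = _cfg(germline_snp_rate=0.0)
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        pairs, _ = emulate_calls(truth, self._perfect_profiles(), cfg, ref)
        for pair in pairs:
            truth_by_class = {
                "snv": {variant_key(t.variant) for t in truth.pairs[pair.tumor_id].variants
                        if t.variant.vclass == "snv"},
                "indel": {variant_key(t.variant) for t in truth.pairs[pair.tumor_id].variants
                          if t.variant.vclass == "indel"},
            }
            for caller, calls in pair.callsets.items():
                prof = default_caller_profiles()[caller]
                expected = set()
                if prof.handles_snv:
                    expected |= truth_by_class["snv"]
                if prof.handles_indel:
                    expected |= truth_by_class["indel"]
                assert {variant_key(c.variant) for c in calls} == expected

    def test_zero_sensitivity_silences_caller(self):
        cfg = _cfg(germline_snp_rate=0.0)
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        profiles = self._perfect_profiles()
        profiles["mutect"] = dataclasses.replace(profiles["mutect"], sens_snv=0.0)
        pairs, _ = emulate_calls(truth, profiles, cfg, ref)
        for pair in pairs:
            assert pair.callsets["mutect"] == []

    def test_binomial_detection_count(self):
        cfg = _cfg(
            germline_snp_rate=0.0, indel_fraction=0.0,
            n_pairs={"carcinoma": 1},
            burden_per_mb_by_group={"carcinoma": 5.0},
            territory_mb_by_group={"carcinoma": 40.0},
        )
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        n_true = len(truth.pairs["T01"].variants)
        profiles = self._perfect_profiles()
        profiles["mutect"] = dataclasses.replace(profiles["mutect"], sens_snv=0.9)
        pairs, _ = emulate_calls(truth, profiles, cfg, ref)
        detected = len(pairs[0].callsets["mutect"])
        sigma = np.sqrt(n_true * 0.9 * 0.1)
        assert abs(detected - 0.9 * n_true) <= 3 * sigma

    def test_missing_profile_rejected(self):
        cfg = _cfg()
        ref = generate_reference(cfg)
        genes = generate_gene_models(cfg, ref)
        truth = simulate_truth(cfg, ref, genes)
        profiles = self._perfect_profiles()
        del profiles["pindel"]
        with pytest.raises(ValueError, match="pindel"):
            emulate_calls(truth, profiles, cfg, ref)


class TestClosedFormConsensus:
    def test_formula_small_cases(self):
        # two callers: P(both) = s1 s2
        assert expected_consensus_snv_sensitivity([0.5, 0.5]) == pytest.approx(0.25)
        # complement check by enumeration over three callers
        s = [0.9, 0.8, 0.7]
        p = 0.0
        for bits in range(8):
            detected = [bool(bits >> i & 1) for i in range(3)]
            if sum(detected) >= 2:
                prob = 1.0
                for si, d in zip(s, detected):
                    prob *= si if d else (1 - si)
                p += prob
        assert expected_consensus_snv_sensitivity(s) == pytest.approx(p)


class TestProfilesAndConfig:
    def test_caller_profiles_cover_all_callers(self):
        profiles = default_caller_profiles()
        assert set(profiles) == set(CALLERS)
        assert not profiles["somaticindeldetector"].handles_snv
        assert not profiles["pindel"].handles_snv
        assert profiles["pindel"].calls_germline_separately
        assert profiles["unifiedgenotyper"].calls_germline_separately

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            CallerProfile("mutect", True, False, sens_snv=1.5)

    def test_cpg_weight_below_one_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(cpg_ct_weight=0.5)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = _cfg(cpg_ct_weight=4.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SimConfig.from_yaml(tmp_path / "cfg.yaml") == cfg
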