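"""The statistical core: counts, tails, RR, threshold scan, permutation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import burdenscan as bs
from burdenscan.errors import ConfigError

from conftest import build_dataset


class TestQualifyingCounts:
    def test_combined_classes_low_threshold(self, meikin_like):
        cfg = bs.AnalysisConfig()
        k, c, carriers = bs.qualifying_counts(meikin_like, "MEIKIN", cfg,
                                              0.11)
        assert (k, c) == (4, 0)
        assert len(carriers) == 4

    def test_missense_only_at_half(self, meikin_like):
        cfg = bs.AnalysisConfig(variant_classes=("missense",))
        k, c, _ = bs.qualifying_counts(meikin_like, "MEIKIN", cfg, 0.5)
        assert (k, c) == (1, 0)     # only the 0.9-score variant passes

    def test_threshold_above_score_range(self, meikin_like):
        cfg = bs.AnalysisConfig(variant_classes=("missense",))
        k, c, carriers = bs.qualifying_counts(meikin_like, "MEIKIN", cfg,
                                              1.01)
        assert (k, c, carriers) == (0, 0, [])

    def test_absent_gene(self, meikin_like):
        cfg = bs.AnalysisConfig()
        assert bs.qualifying_counts(meikin_like, "NOPE", cfg, 0.0) \
            == (0, 0, [])

    def test_crc_only_excludes_polyp_cases_entirely(self):
        # carrier case_00003 has phenotype polyp (n_crc=2): under crc_only
        # it is dropped from the analysis, not recycled as a control
        obs = [("case_00001", "G1", "lof", None),
               ("case_00003", "G1", "lof", None)]
        d = build_dataset(3, 10, obs, n_crc=2)
        cfg = bs.AnalysisConfig(variant_classes=("lof",),
                                case_subset="crc_only")
        k, c, _ = bs.qualifying_counts(d, "G1", cfg, None)
        assert (k, c) == (1, 0)


class TestBinomialTail:
    def test_two_of_two_closed_form(self):
        p = bs.binomial_burden_p(2, 2, 212, 31911)
        assert p == pytest.approx((212 / 31911) ** 2, rel=1e-12)

    def test_three_of_ten_brute_force(self):
        pi = 174 / 31873
        brute = sum(math.comb(10, k) * pi ** k * (1 - pi) ** (10 - k)
                    for k in range(3, 11))
        assert bs.binomial_burden_p(3, 10, 174, 31873) \
            == pytest.approx(brute, rel=1e-10)
        assert brute == pytest.approx(1.90e-5, rel=0.02)

    def test_zero_count_and_empty_support(self):
        assert bs.binomial_burden_p(0, 5, 10, 100) == 1.0
        assert bs.binomial_burden_p(0, 0, 10, 100) == 1.0

    def test_monotone_in_k(self):
        ps = [bs.binomial_burden_p(k, 10, 100, 1000) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigError):
            bs.binomial_burden_p(5, 3, 10, 100)


class TestRelativeRisk:
    @pytest.mark.parametrize("k,n_case,c,n_control,expected", [
        (4, 212, 0, 31699, 150.5),      # case rate / pooled rate
        (3, 174, 7, 31699, 55.0),
        (3, 174, 6, 31699, 61.1),
        (4, 212, 17, 31699, 28.7),
        (4, 212, 19, 31699, 26.2),
        (1, 100, 99, 9900, 1.0),        # case rate equals pooled rate
    ])
    def test_pooled_form(self, k, n_case, c, n_control, expected):
        rr = bs.relative_risk_pooled(k, n_case, c, n_control)
        assert round(rr, 1) == expected

    def test_undefined_without_observations(self):
        with pytest.raises(ConfigError):
            bs.relative_risk_pooled(0, 100, 0, 1000)

    @given(k=st.integers(0, 50), c=st.integers(0, 500),
           n_case=st.integers(10, 1000), n_extra=st.integers(10, 50_000))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_pooled_identity_holds_to_ten_digits(self, k, c, n_case,
                                                 n_extra):
        if k + c == 0:
            return
        n_control = n_extra
        rr = bs.relative_risk_pooled(k, n_case, c, n_control)
        direct = (k / n_case) / ((k + c) / (n_case + n_control))
        assert rr == pytest.approx(direct, rel=1e-10)


class TestVariableThresholdScan:
    def test_three_candidate_example(self):
        obs = [("case_00001", "G1", "missense", 0.9),
               ("case_00002", "G1", "missense", 0.6),
               ("control_00001", "G1", "missense", 0.3)]
        d = build_dataset(100, 900, obs)
        cfg = bs.AnalysisConfig(variant_classes=("missense",))
        scan = bs.variable_threshold_scan(d, "G1", cfg)
        # p(0.9)=0.1, p(0.6)=0.01, p(0.3)=P(X>=2|m=3,pi=0.1)=0.028
        assert scan.threshold == pytest.approx(0.6)
        assert scan.p == pytest.approx(0.01, rel=1e-9)
        assert (scan.k, scan.c) == (2, 0)

    def test_single_candidate(self):
        d = build_dataset(100, 900, [("case_00001", "G1", "missense", 0.4)])
        cfg = bs.AnalysisConfig(variant_classes=("missense",))
        scan = bs.variable_threshold_scan(d, "G1", cfg)
        assert scan.threshold == pytest.approx(0.4)
        assert scan.p == pytest.approx(0.1, rel=1e-12)

    def test_no_missense_degenerates_to_lof_only(self):
        d = build_dataset(100, 900, [("case_00001", "G1", "lof", None)])
        cfg = bs.AnalysisConfig(variant_classes=("missense", "lof"))
        scan = bs.variable_threshold_scan(d, "G1", cfg)
        assert scan.threshold is None
        assert scan.p == pytest.approx(0.1, rel=1e-12)

    def test_scan_never_beaten_by_any_fixed_threshold(self):
        rng = np.random.default_rng(42)
        cfg = bs.AnalysisConfig(variant_classes=("missense", "lof"))
        for trial in range(200):
            n_obs = rng.integers(1, 9)
            obs = []
            for i in range(n_obs):
                in_case = rng.random() < 0.3
                sid = (f"case_{rng.integers(1, 21):05d}" if in_case
                       else f"control_{rng.integers(1, 181):05d}")
                if rng.random() < 0.3:
                    obs.append((sid, "G1", "lof", None))
                else:
                    obs.append((sid, "G1", "missense",
                                float(np.round(rng.random(), 3))))
            d = build_dataset(20, 180, obs)
            scan = bs.variable_threshold_scan(d, "G1", cfg)
            fixed = [bs.qualifying_counts(d, "G1", cfg, t)
                     for t in np.linspace(0, 1, 21)]
            for k, c, _ in fixed:
                p_fixed = bs.binomial_burden_p(k, k + c, 20, 200)
                assert scan.p <= p_fixed + 1e-12


class TestPermutation:
    def test_all_permutations_win_gives_one(self):
        # k = 0 observed: every shuffle does at least as well
        d = build_dataset(10, 90, [("control_00001", "G1", "lof", None)])
        cfg = bs.AnalysisConfig(variant_classes=("lof",),
                                n_permutations=500, seed=3)
        assert bs.permutation_corrected_p(d, "G1", cfg) == 1.0

    def test_floor_when_no_permutation_beats_observed(self, meikin_like):
        cfg = bs.AnalysisConfig(seed=2, n_permutations=100_000)
        p, r, n, ties = bs.permutation_corrected_p(
            meikin_like, "MEIKIN", cfg, early_exit_r=None,
            return_details=True)
        assert r == 0
        assert p == pytest.approx(1 / (100_000 + 1), rel=1e-12)

    def test_in_valid_range_and_seed_reproducible(self):
        obs = [("case_00001", "G1", "missense", 0.8),
               ("control_00001", "G1", "missense", 0.5),
               ("control_00002", "G1", "lof", None)]
        d = build_dataset(30, 270, obs)
        cfg = bs.AnalysisConfig(seed=9, n_permutations=2000)
        p1 = bs.permutation_corrected_p(d, "G1", cfg)
        p2 = bs.permutation_corrected_p(d, "G1", cfg)
        assert p1 == p2
        assert 1 / 2001 <= p1 <= 1.0

    def test_agrees_with_hypergeometric_oracle(self):
        # single-variant-per-carrier, fixed threshold: the case-carrier
        # count is hypergeometric under label shuffling
        rng = np.random.default_rng(11)
        n_perm = 200_000
        for trial in range(5):
            K = int(rng.integers(3, 8))
            k_obs = int(rng.integers(1, K + 1))
            n_case, n_control = 100, 1900
            obs = [(f"case_{i:05d}" if i <= k_obs else
                    f"control_{i:05d}", "G1", "lof", None)
                   for i in range(1, K + 1)]
            d = build_dataset(n_case, n_control, obs)
            cfg = bs.AnalysisConfig(variant_classes=("lof",), seed=trial,
                                    n_permutations=n_perm)
            p_hat = bs.permutation_corrected_p(d, "G1", cfg,
                                               early_exit_r=None)
            oracle = bs.exact_permutation_oracle(K, k_obs, n_case,
                                                 n_case + n_control)
            se = math.sqrt(oracle * (1 - oracle) / n_perm)
            assert abs(p_hat - oracle) <= 3 * se + 2 / n_perm

    def test_strict_policy_excludes_ties(self):
        d = build_dataset(10, 90, [("case_00001", "G1", "lof", None)])
        cfg = bs.AnalysisConfig(variant_classes=("lof",), seed=1,
                                n_permutations=5000)
        p_incl, r_incl, n, ties = bs.permutation_corrected_p(
            d, "G1", cfg, early_exit_r=None, return_details=True)
        p_strict, r_strict, _, _ = bs.permutation_corrected_p(
            d, "G1", cfg, tie_policy="strict", early_exit_r=None,
            return_details=True)
        assert ties > 0
        assert r_incl == r_strict + ties
        assert p_strict < p_incl

    def test_bad_iteration_count_rejected(self, meikin_like):
        cfg = bs.AnalysisConfig(n_permutations=0)
        with pytest.raises(ConfigError):
            bs.permutation_corrected_p(meikin_like, "MEIKIN", cfg)


class TestHypergeometricOracle:
    def test_two_of_two_product_form(self):
        p = bs.exact_permutation_oracle(2, 2, 212, 31911)
        assert p == pytest.approx((212 * 211) / (31911 * 31910), rel=1e-12)

    def test_zero_observed_is_one(self):
        assert bs.exact_permutation_oracle(5, 0, 212, 31911) == 1.0

    def test_tail_sum_matches_scipy_direct(self):
        got = bs.exact_permutation_oracle(10, 3, 174, 31873)
        brute = sum(math.comb(10, x) * math.comb(31863, 174 - x)
                    for x in range(3, 11)) / math.comb(31873, 174)
        assert got == pytest.approx(brute, rel=1e-9)


class TestGeneSet:
    def _toy(self):
        obs = [("case_00001", "ONC1", "lof", None),
               ("case_00001", "TSG1", "lof", None),
               ("case_00002", "TSG1", "missense", 0.7),
               ("control_00001", "TSG1", "missense", 0.3),
               ("control_00002", "ONC1", "missense", 0.9)]
        d = build_dataset(10, 100, obs)
        roles = {"ONC1": bs.GeneAnnotation("ONC1", "oncogene"),
                 "TSG1": bs.GeneAnnotation("TSG1", "tsg")}
        return d, roles

    def test_oncogene_lof_excluded(self):
        d, roles = self._toy()
        cfg = bs.AnalysisConfig()
        r = bs.geneset_burden(d, ["ONC1"], roles, "lof", cfg)
        assert (r.k, r.c) == (0, 0)
        assert r.p == 1.0 and math.isnan(r.rr)
        assert r.flag == "no_qualifying_variants"

    def test_combined_is_union_of_rules(self):
        d, roles = self._toy()
        cfg = bs.AnalysisConfig()
        genes = ["ONC1", "TSG1"]
        lof = bs.geneset_burden(d, genes, roles, "lof", cfg)
        mis = bs.geneset_burden(d, genes, roles, "missense_vest_ge_0.5",
                                cfg)
        both = bs.geneset_burden(d, genes, roles, "combined", cfg)
        assert both.k + both.c == (lof.k + lof.c) + (mis.k + mis.c)

    def test_table2_magnitude_arithmetic(self):
        rr = bs.relative_risk_pooled(9, 212, 179, 31699)
        assert rr == pytest.approx(7.21, abs=0.02)

    def test_missing_role_rejected(self):
        d, roles = self._toy()
        with pytest.raises(ConfigError, match="missing role"):
            bs.geneset_burden(d, ["TSG1", "GHOST"], roles, "lof",
                              bs.AnalysisConfig())


class TestMultipleTesting:
    @pytest.mark.parametrize("alpha,n,bonf,border", [
        (0.05, 18500, 2.70e-6, 5.41e-5),
        (0.05, 18200, 2.75e-6, 5.49e-5),
        (0.05, 1, 0.05, 1.0),
    ])
    def test_thresholds(self, alpha, n, bonf, border):
        b, bl = bs.multiple_testing_thresholds(alpha, n)
        assert b == pytest.approx(bonf, rel=0.01)
        assert bl == pytest.approx(border, rel=0.01)


class TestAnalysisSuite:
    def _signal_dataset(self):
        obs = ([(f"case_{i:05d}", "SIG", "lof", None) for i in (1, 2, 3)]
               + [("control_00001", "SIG", "missense", 0.2),
                  ("control_00002", "SIG", "missense", 0.4),
                  ("case_00004", "NULLG", "missense", 0.5),
                  ("control_00003", "NULLG", "missense", 0.6),
                  ("control_00004", "NULLG", "missense", 0.7)])
        return build_dataset(30, 3000, obs, n_crc=25)

    def test_lof_signal_best_analysis_contains_lof(self):
        d = self._signal_dataset()
        cfg = bs.AnalysisConfig(seed=4, n_permutations=999)
        results = bs.run_analysis_suite(d, cfg)
        best = {r.gene: r for r in results if r.best}
        assert "LoF" in best["SIG"].analysis

    def test_gene_without_qualifying_variants_six_unit_results(self):
        d = build_dataset(5, 50, [("case_00001", "EMPTY", "other", None)])
        cfg = bs.AnalysisConfig(seed=0, n_permutations=99)
        results = bs.run_analysis_suite(d, cfg, genes=["EMPTY"])
        assert len(results) == 6
        assert all(r.p_binomial == 1.0 and r.p_permutation == 1.0
                   for r in results)

    def test_results_invariant_to_gene_order(self):
        d = self._signal_dataset()
        cfg = bs.AnalysisConfig(seed=4, n_permutations=499)
        fwd = bs.run_analysis_suite(d, cfg, genes=["NULLG", "SIG"])
        rev = bs.run_analysis_suite(d, cfg, genes=["SIG", "NULLG"])
        key = lambda r: (r.gene, r.analysis)
        assert sorted([r.to_dict() for r in fwd], key=lambda x: (x["gene"], x["analysis"])) \
            == sorted([r.to_dict() for r in rev], key=lambda x: (x["gene"], x["analysis"]))


class TestReplication:
    def test_rescan_at_least_as_significant_on_same_data(self, meikin_like):
        cfg = bs.AnalysisConfig(seed=1)
        fixed, rescanned = bs.replicate_gene(meikin_like, "MEIKIN", 0.5,
                                             cfg)
        assert rescanned.p_binomial <= fixed.p_binomial

    def test_absent_gene_flagged(self):
        d = build_dataset(5, 50, [("case_00001", "G1", "lof", None)])
        cfg = bs.AnalysisConfig(seed=1)
        fixed, rescanned = bs.replicate_gene(d, "GHOST", 0.3, cfg)
        assert fixed.flag == rescanned.flag == "gene_absent"
        assert fixed.p_binomial == rescanned.p_binomial == 1.0

    def test_planted_effect_replicates_at_fixed_threshold(self):
        params = bs.SimulationParams(
            n_case=200, n_control=5000, n_genes=5, synonymous_rate=0.0,
            inframe_rate=0.0, background_deleterious_rate=0.002,
            qc_fail_fraction=0.0,
            planted_genes=(bs.PlantedGene("RISK", 0.05, 2e-4, 0.0,
                                          vest_alpha=6, vest_beta=2),),
            seed=31)
        hits = 0
        for i in range(20):
            d, _ = bs.simulate_cohort(params.replace(
                seed=bs.simulate._spawn_seed(31, i)))
            fixed, _ = bs.replicate_gene(
                d, "RISK", 0.5,
                bs.AnalysisConfig(variant_classes=("missense",), seed=i))
            hits += fixed.p_binomial < 0.05
        assert hits >= 15   # ~10 expected case carriers vs ~1 in controls
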