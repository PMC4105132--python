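import math
import random

import numpy as np
import pytest
import scipy.stats

from charkit import codon_usage as cu
from charkit import synthetic as syn
from charkit.seq_core import CharkitError, SequenceRecord

from oracles import nc_direct, pearson_brute


def _random_cds(rng, n_codons):
    sense = list(cu.SENSE_CODONS)
    return "".join(rng.choice(sense) for _ in range(n_codons))


class TestCountCodons:
    def test_plain_counting(self):
        t = cu.count_codons("ATGGCC")
        assert t.counts == {"ATG": 1, "GCC": 1} and t.n_codons == 2

    def test_trailing_partial_skipped(self):
        t = cu.count_codons("ATGGC")
        assert t.counts == {"ATG": 1} and t.skipped == 1

    def test_n_codon_skipped(self):
        t = cu.count_codons("ATGNNA")
        assert t.counts == {"ATG": 1} and t.skipped == 1

    def test_stop_codons_tracked_separately(self):
        t = cu.count_codons("ATGTAA")
        assert t.counts == {"ATG": 1} and t.stop_counts == {"TAA": 1}
        assert t.n_codons == 1


class TestRscu:
    def test_two_fold_family_values(self):
        t = cu.count_codons("GAA" * 3 + "GAG")
        r = cu.rscu(t)
        assert r["GAA"] == pytest.approx(1.5)
        assert r["GAG"] == pytest.approx(0.5)

    def test_uniform_usage_gives_ones(self):
        cds = "".join(
            "".join(codons) for codons in cu.DEGENERATE_FAMILIES.values()
        )
        r = cu.rscu(cu.count_codons(cds))
        assert all(v == pytest.approx(1.0) for v in r.values())

    def test_exclusive_codon_in_four_fold_family(self):
        r = cu.rscu(cu.count_codons("GGC" * 5))
        assert r["GGC"] == pytest.approx(4.0)
        assert r["GGA"] == 0.0

    def test_zero_families_reported_missing(self):
        r = cu.rscu(cu.count_codons("ATG"))
        assert "GAA" not in r

    def test_family_sums_equal_family_size(self):
        rng = random.Random(11)
        for _ in range(10):
            r = cu.rscu(cu.count_codons(_random_cds(rng, 400)))
            for aa, codons in cu.FAMILIES.items():
                vals = [r[c] for c in codons if c in r]
                if vals:
                    assert sum(vals) == pytest.approx(len(codons))


class TestGc3:
    @pytest.mark.parametrize(
        "cds,expected", [("ATGGGG", 1.0), ("GGAGGT", 0.0), ("GGCGGA", 0.5)]
    )
    def test_direct(self, cds, expected):
        assert cu.gc3(cds) == pytest.approx(expected)

    def test_n_codons_excluded(self):
        assert cu.gc3("GGCGNN") == pytest.approx(1.0)

    def test_no_complete_codon_is_error(self):
        with pytest.raises(CharkitError):
            cu.gc3("AT")


class TestEffectiveNumberOfCodons:
    def test_maximal_bias_is_exactly_20(self):
        # every amino acid from a single fixed codon, n >= 2 each
        cds = "".join(codons[0] * 3 for codons in cu.FAMILIES.values())
        assert cu.effective_number_of_codons(cu.count_codons(cds)) == 20.0

    def test_uniform_usage_limit_is_exactly_61(self):
        cds = "".join(
            "".join(c * 4 for c in codons)
            for codons in cu.DEGENERATE_FAMILIES.values()
        )
        t = cu.count_codons(cds)
        assert cu.effective_number_of_codons(t, estimator="population") == 61.0
        # the finite-sample estimator overshoots and clamps at the ceiling
        assert cu.effective_number_of_codons(t) == 61.0

    def test_matches_direct_definition_oracle(self):
        rng = random.Random(5)
        for _ in range(25):
            cds = _random_cds(rng, 2000)
            nc = cu.effective_number_of_codons(cu.count_codons(cds))
            assert nc == pytest.approx(nc_direct(cds), abs=1e-9)

    def test_sparse_input_uses_fallback(self):
        # only two-fold families present: other classes take the
        # count-weighted fallback and Nc stays in [20, 61]
        nc = cu.effective_number_of_codons(cu.count_codons("GAAGAGGAAGAG"))
        assert 20.0 <= nc <= 61.0

    def test_no_computable_family_is_error(self):
        with pytest.raises(CharkitError):
            cu.effective_number_of_codons(cu.count_codons("ATG"))


class TestExpectedNc:
    def test_midpoint_value(self):
        assert cu.expected_nc(0.5) == pytest.approx(60.5)

    def test_limit_toward_zero(self):
        assert cu.expected_nc(1e-9) == pytest.approx(31.0, abs=1e-6)

    def test_rational_component_symmetric(self):
        for s in (0.1, 0.25, 0.4):
            assert cu.expected_nc(s) - s == pytest.approx(
                cu.expected_nc(1 - s) - (1 - s)
            )

    @pytest.mark.parametrize("s", [0.0, 1.0, -0.1, 1.5])
    def test_domain_is_open_interval(self, s):
        with pytest.raises(CharkitError):
            cu.expected_nc(s)


def _optimal_alphabetical():
    return frozenset(codons[0] for codons in cu.DEGENERATE_FAMILIES.values())


class TestCodonBiasIndex:
    def test_all_optimal_gives_one(self):
        cds = "".join(codons[0] * 2 for codons in cu.DEGENERATE_FAMILIES.values())
        cbi = cu.codon_bias_index(cu.count_codons(cds), _optimal_alphabetical())
        assert cbi == pytest.approx(1.0)

    def test_uniform_usage_gives_zero(self):
        cds = "".join(
            "".join(codons) for codons in cu.DEGENERATE_FAMILIES.values()
        )
        cbi = cu.codon_bias_index(cu.count_codons(cds), _optimal_alphabetical())
        assert cbi == pytest.approx(0.0)

    def test_avoiding_optimal_in_two_fold_families_is_minus_one(self):
        # 2-fold families only, always the non-optimal codon:
        # N_opt=0, N_ran=n/2, N_tot=n -> CBI = -1
        two_fold = {
            aa: c for aa, c in cu.DEGENERATE_FAMILIES.items() if len(c) == 2
        }
        cds = "".join(codons[1] * 5 for codons in two_fold.values())
        cbi = cu.codon_bias_index(cu.count_codons(cds), _optimal_alphabetical())
        assert cbi == pytest.approx(-1.0)

    def test_invalid_optimal_set_rejected(self):
        with pytest.raises(CharkitError):
            cu.codon_bias_index(cu.count_codons("GAAGAG"), frozenset({"GAA"}))


class TestSelectOptimalCodons:
    def test_high_expression_preference_recovered(self):
        # high-expression genes use alphabetically-last codons; low use first
        hi = "".join(codons[-1] * 4 for codons in cu.DEGENERATE_FAMILIES.values())
        lo = "".join(codons[0] * 4 for codons in cu.DEGENERATE_FAMILIES.values())
        tables = {"hi": cu.count_codons(hi)} | {
            f"lo{i}": cu.count_codons(lo) for i in range(9)
        }
        expression = [
            cu.ExpressionRecord.from_counts("hi", 1000, 300, 2000)
        ] + [
            cu.ExpressionRecord.from_counts(f"lo{i}", 10, 300, 2000)
            for i in range(9)
        ]
        optimal = cu.select_optimal_codons(tables, expression, top_fraction=0.10)
        assert optimal == frozenset(
            codons[-1] for codons in cu.DEGENERATE_FAMILIES.values()
        )

    def test_top_fraction_one_pools_everything(self):
        t = {"g": cu.count_codons("GAAGAAGAG")}
        e = [cu.ExpressionRecord.from_counts("g", 5, 9, 10)]
        optimal = cu.select_optimal_codons(t, e, top_fraction=1.0)
        assert "GAA" in optimal

    def test_empty_intersection_is_error(self):
        with pytest.raises(CharkitError):
            cu.select_optimal_codons(
                {"g": cu.count_codons("GAA")},
                [cu.ExpressionRecord.from_counts("other", 1, 3, 10)],
            )


class TestFpkm:
    def test_formula(self):
        assert cu.fpkm(10, 1000, 10**6) == pytest.approx(10.0)

    def test_zero_count(self):
        assert cu.fpkm(0, 500, 100) == 0.0

    def test_scaling_identities(self):
        base = cu.fpkm(7, 433, 123457)
        assert cu.fpkm(14, 433, 123457) == pytest.approx(2 * base)
        assert cu.fpkm(7, 866, 123457) == pytest.approx(base / 2)
        assert cu.fpkm(7, 433, 2 * 123457) == pytest.approx(base / 2)

    def test_invalid_inputs(self):
        with pytest.raises(CharkitError):
            cu.fpkm(1, 0, 10)
        with pytest.raises(CharkitError):
            cu.fpkm(1, 10, 0)


class TestPearson:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, p = cu.pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)

    def test_orthogonalized_vector_gives_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        y = y - (np.dot(x - x.mean(), y) / np.dot(x - x.mean(), x - x.mean())) * (
            x - x.mean()
        )
        r, _ = cu.pearson(x, y)
        assert abs(r) < 1e-12

    def test_toy_vectors_match_direct_formula(self):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [2.0, 3.0, 1.0, 7.0, 9.0]
        r, p = cu.pearson(x, y)
        r_expect = pearson_brute(x, y)
        assert r == pytest.approx(r_expect)
        t = r_expect * math.sqrt(3 / (1 - r_expect**2))
        p_expect = 2 * scipy.stats.t.sf(abs(t), df=3)
        assert p == pytest.approx(p_expect, rel=1e-6)

    def test_constant_vector_is_error(self):
        with pytest.raises(CharkitError):
            cu.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBiasExpressionAnalysis:
    def test_coupled_bias_yields_positive_correlation(self):
        records, truth = syn.gen_cds_set(300, 250, 0.6, (0.0, 0.9), seed=21)
        expression = syn.gen_expression(truth, coupling=0.8, seed=22)
        df, (r, p) = cu.bias_expression_analysis(records, expression)
        assert r > 0 and p < 0.01

    def test_uncoupled_bias_yields_small_correlation(self):
        records, truth = syn.gen_cds_set(300, 250, 0.6, (0.0, 0.9), seed=31)
        expression = syn.gen_expression(truth, coupling=0.0, seed=32)
        _, (r, _) = cu.bias_expression_analysis(records, expression)
        assert abs(r) < 0.2

    def test_single_gene_is_error(self):
        records, truth = syn.gen_cds_set(1, 200, 0.5, 0.2, seed=1)
        expression = syn.gen_expression(truth, coupling=0.0, seed=2)
        with pytest.raises(CharkitError):
            cu.bias_expression_analysis(records, expression)

    def test_order_invariance(self):
        records, truth = syn.gen_cds_set(40, 200, 0.5, (0.0, 0.5), seed=41)
        expression = syn.gen_expression(truth, coupling=0.5, seed=42)
        df1, rp1 = cu.bias_expression_analysis(records, expression)
        df2, rp2 = cu.bias_expression_analysis(
            list(reversed(records)), list(reversed(expression))
        )
        assert rp1 == pytest.approx(rp2)
        merged = df1.merge(df2, on="id", suffixes=("_a", "_b"))
        assert np.allclose(merged["nc_a"], merged["nc_b"])
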