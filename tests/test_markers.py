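import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grnstates as g
from grnstates.io import ValidationError

from oracles import fisher_enumeration, wilcoxon_enumeration


class TestLinCCC:
    def test_perfect_concordance(self):
        res = g.lin_ccc([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.estimate == pytest.approx(1.0)

    def test_hand_computed_shifted_line(self):
        res = g.lin_ccc([1, 2, 3], [2, 3, 4])
        assert res.estimate == pytest.approx(4 / 7)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_perfect_discordance(self):
        res = g.lin_ccc([1, 2, 3], [3, 2, 1])
        assert res.estimate == pytest.approx(-1.0)

    def test_equal_moments_reduces_to_pearson(self, rng):
        x = rng.normal(0, 1, 100)
        y = 0.6 * x + rng.normal(0, 0.8, 100)
        # force matching first two moments
        y = (y - y.mean()) / y.std() * x.std() + x.mean()
        ccc = g.lin_ccc(x, y).estimate
        r = g.pearson_corr(x, y).estimate
        assert ccc == pytest.approx(r, abs=1e-10)

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(100):
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 30)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 30)
            assert abs(g.lin_ccc(x, y).estimate) <= abs(g.pearson_corr(x, y).estimate) + 1e-12

    def test_bootstrap_ci_brackets_estimate(self, rng):
        x = rng.uniform(0, 200, 40)
        y = x + rng.normal(0, 20, 40)
        res = g.lin_ccc(x, y, ci_method="bootstrap", n_boot=300, seed=0)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_double_constant_rejected(self):
        with pytest.raises(ValidationError):
            g.lin_ccc([1, 1, 1], [2, 2, 2])


class TestPearson:
    def test_affine_relation(self):
        x = np.arange(10.0)
        assert g.pearson_corr(x, 2 * x + 1).estimate == pytest.approx(1.0)
        assert g.pearson_corr(x, -x).estimate == pytest.approx(-1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValidationError):
            g.pearson_corr([1, 1, 1], [1, 2, 3])


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p, tier = g.wilcoxon_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)
        assert tier == "ns"

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            nx = int(rng.integers(2, 5))
            ny = int(rng.integers(2, 9 - nx))
            pool = rng.permutation(100)[:nx + ny].astype(float)  # distinct, no ties
            x, y = pool[:nx], pool[nx:]
            _, p, _ = g.wilcoxon_test(x, y)
            assert p == pytest.approx(wilcoxon_enumeration(x, y), abs=1e-12)

    def test_paired_identical_gives_p_one(self):
        _, p, tier = g.wilcoxon_test([1, 2, 3], [1, 2, 3], paired=True)
        assert p == 1.0
        assert tier == "ns"

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            g.wilcoxon_test([1, 2], [1, 2, 3], paired=True)

    def test_tier_thresholds(self):
        assert g.wilcoxon_test(list(range(20)), [x + 100 for x in range(20)])[2] == "****"


class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(g.benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(g.benjamini_hochberg([0.2]), [0.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, ps):
        adj = g.benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1 + 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            g.benjamini_hochberg([0.5, 1.5])


class TestOverlapFisher:
    def test_closed_form_full_overlap(self):
        res = g.overlap_fisher(list("abcde"), list("abcde"),
                               [chr(97 + i) for i in range(20)])
        assert res.p == pytest.approx(1 / 15504)
        assert res.n_overlap == 5

    def test_disjoint_sets_near_one(self):
        uni = [f"g{i}" for i in range(1000)]
        res = g.overlap_fisher(uni[:5], uni[500:505], uni)
        assert res.p > 0.9

    def test_matches_enumeration_for_small_universe(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            u = int(rng.integers(4, 13))
            uni = [f"g{i}" for i in range(u)]
            na = int(rng.integers(1, u))
            nb = int(rng.integers(1, u))
            A = list(rng.choice(uni, na, replace=False))
            B = list(rng.choice(uni, nb, replace=False))
            res = g.overlap_fisher(A, B, uni)
            expected = fisher_enumeration(na, nb, len(set(A) & set(B)), u)
            assert res.p == pytest.approx(expected, rel=1e-9)

    def test_stray_elements_rejected(self):
        with pytest.raises(ValidationError, match="zzz"):
            g.overlap_fisher(["a", "zzz"], ["a"], ["a", "b"])


class TestHurdleDE:
    @staticmethod
    def _null_expr(rng, n_genes=400, n_per=150):
        counts = rng.negative_binomial(10, 10 / 13, size=(n_genes, 2 * n_per))
        em = g.ExpressionMatrix(counts, [f"g{i}" for i in range(n_genes)],
                                [f"c{i}" for i in range(2 * n_per)])
        return g.lognormalize(em), n_per

    def test_null_type_one_error_controlled(self, rng):
        ln, n_per = self._null_expr(rng)
        de = g.hurdle_de(ln, ln.cell_ids[:n_per], ln.cell_ids[n_per:])
        frac = (de["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(de))
        assert frac <= 0.05 + 3 * se  # 3 SE at this small gene count

    def test_planted_shift_recovered(self, rng):
        n_per = 200
        counts = rng.negative_binomial(10, 10 / 13, size=(50, 2 * n_per)).astype(float)
        counts[0, :n_per] = rng.negative_binomial(10, 10 / 22, size=n_per)  # 4x mean
        em = g.ExpressionMatrix(counts, [f"g{i}" for i in range(50)],
                                [f"c{i}" for i in range(2 * n_per)])
        ln = g.lognormalize(em)
        de = g.hurdle_de(ln, ln.cell_ids[:n_per], ln.cell_ids[n_per:]).set_index("gene")
        assert de.loc["g0", "p_adj"] < 0.01
        assert de.loc["g0", "log2FC"] == pytest.approx(2.0, abs=0.5)

    def test_detection_only_gene_finite_fc(self, rng):
        n_per = 50
        counts = rng.negative_binomial(10, 10 / 13, size=(20, 2 * n_per)).astype(float)
        counts[0, n_per:] = 0  # detected only in group A
        em = g.ExpressionMatrix(counts, [f"g{i}" for i in range(20)],
                                [f"c{i}" for i in range(2 * n_per)])
        ln = g.lognormalize(em)
        de = g.hurdle_de(ln, ln.cell_ids[:n_per], ln.cell_ids[n_per:]).set_index("gene")
        assert np.isfinite(de.loc["g0", "log2FC"])
        assert de.loc["g0", "p_adj"] < 1e-6
        assert de.loc["g0", "det_frac_B"] == 0.0

    def test_all_zero_gene_excluded(self, rng):
        counts = rng.negative_binomial(10, 10 / 13, size=(10, 20)).astype(float)
        counts[3] = 0
        em = g.ExpressionMatrix(counts, [f"g{i}" for i in range(10)],
                                [f"c{i}" for i in range(20)])
        ln = g.lognormalize(em)
        with pytest.warns(UserWarning, match="excluded"):
            de = g.hurdle_de(ln, ln.cell_ids[:10], ln.cell_ids[10:])
        assert "g3" not in set(de["gene"])


class TestCrossCohort:
    @staticmethod
    def _de(genes, fc, p_adj):
        return pd.DataFrame({"gene": genes, "log2FC": fc, "p_adj": p_adj})

    def test_infinite_threshold_empties_sets(self):
        de = self._de(["a", "b"], [3.0, 2.0], [1e-5, 1e-5])
        res = g.cross_cohort_compare(de, de, fc_threshold=np.inf)
        assert not res["shared"]
        assert res["overlap"].p == pytest.approx(1.0)

    def test_shared_sets_subset_of_significant(self):
        de1 = self._de(list("abcd"), [1.0, 1.0, 0.1, 1.0], [0.001] * 4)
        de2 = self._de(list("abcd"), [1.0, 0.1, 1.0, 1.0], [0.001] * 4)
        res = g.cross_cohort_compare(de1, de2)
        assert res["shared"] <= res["sig_cohort1"]
        assert res["shared"] <= res["sig_cohort2"]
        assert res["shared"] == {"a", "d"}

    def test_empty_universe_rejected(self):
        de1 = self._de(["a"], [1.0], [0.01])
        de2 = self._de(["b"], [1.0], [0.01])
        with pytest.raises(ValidationError):
            g.cross_cohort_compare(de1, de2)
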