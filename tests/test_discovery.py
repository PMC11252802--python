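import numpy as np
import pandas as pd
import pytest

import grnstates as g
from grnstates.activity import ActivityMatrix
from grnstates.discovery import cluster_dendrogram
from grnstates.io import ValidationError

from oracles import ari_pair_counting, jsd_summation


def _activity(values, cells=None):
    values = np.asarray(values, dtype=float)
    regs = [f"R{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ActivityMatrix(values, regs, cells, params={})


def _partition(labels, cells):
    s = pd.Series(labels, index=cells, name="grn")
    return g.GRNPartition(s, s.nunique(), None,
                          pd.DataFrame(columns=["k", "mean_ari", "sd_ari"]))


class TestAdjustedRandIndex:
    def test_identical_and_relabel_invariance(self):
        assert g.adjusted_rand_index([1, 1, 2, 3], [1, 1, 2, 3]) == 1.0
        assert g.adjusted_rand_index([1, 1, 2, 3], [7, 7, 5, 2]) == 1.0

    def test_hand_contingency_value(self):
        assert g.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 4, n)
            assert g.adjusted_rand_index(a, b) == pytest.approx(
                ari_pair_counting(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            g.adjusted_rand_index([1, 2], [1, 2, 3])


class TestDendrogram:
    def test_coincident_pair_merges_first_at_zero(self):
        act = _activity(np.array([[0.0, 0.0, 1.0], [0.2, 0.2, 0.9]]))
        dend = cluster_dendrogram(act)
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(dend.linkage_matrix[0, :2]) == {0.0, 1.0}

    def test_heights_nondecreasing(self, rng):
        act = _activity(rng.uniform(0, 1, size=(4, 30)))
        dend = cluster_dendrogram(act)
        heights = dend.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_planted_blocks_recovered_at_k(self, rng):
        blocks = np.zeros((3, 90))
        for i in range(3):
            blocks[i, i * 30:(i + 1) * 30] = 1.0
        act = _activity(np.clip(blocks + rng.normal(0, 0.05, blocks.shape), 0, 1))
        dend = cluster_dendrogram(act)
        labels = dend.cut(3)
        truth = np.repeat([0, 1, 2], 30)
        assert g.adjusted_rand_index(labels, truth) == 1.0


class TestSelectCut:
    def test_recovers_planted_k(self, small_activity, small_cohort):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 8),
                                   n_resamples=15, seed=0)
        assert part.n_grns == 3
        truth = small_cohort["truth"].state_of_cell.reindex(part.labels.index)
        assert g.adjusted_rand_index(part.labels, truth) > 0.9

    def test_degenerate_input_single_grn(self):
        act = _activity(np.full((3, 20), 0.5))
        with pytest.warns(UserWarning, match="identical"):
            part = g.select_cut_by_ari(act, k_range=range(2, 5), n_resamples=3, seed=0)
        assert part.n_grns == 1
        assert part.ari_profile.empty

    def test_seed_determinism(self, small_activity):
        a = g.select_cut_by_ari(small_activity, k_range=range(2, 6), n_resamples=8, seed=3)
        b = g.select_cut_by_ari(small_activity, k_range=range(2, 6), n_resamples=8, seed=3)
        pd.testing.assert_frame_equal(a.ari_profile, b.ari_profile)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_cut_height_realizes_k(self, small_activity):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=8, seed=0)
        dend = part.dendrogram
        heights = dend.linkage_matrix[:, 2]
        n_above = int(np.sum(heights > dend.cut_height))
        assert n_above + 1 == part.n_grns


class TestRegulonSpecificity:
    def test_uniform_indicator_gives_one(self):
        cells = [f"c{i}" for i in range(6)]
        act = _activity(np.array([[1, 1, 1, 0, 0, 0.0]]), cells)
        part = _partition(["GRN1"] * 3 + ["GRN2"] * 3, cells)
        rss = g.regulon_specificity(act, part).set_index(["regulon", "grn"])["rss"]
        assert rss[("R0", "GRN1")] == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        cells = [f"c{i}" for i in range(6)]
        act = _activity(np.array([[0, 0, 0, 1, 1, 1.0]]), cells)
        part = _partition(["GRN1"] * 3 + ["GRN2"] * 3, cells)
        rss = g.regulon_specificity(act, part).set_index(["regulon", "grn"])["rss"]
        assert rss[("R0", "GRN1")] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_activity_matches_jsd_oracle(self):
        n = 10
        cells = [f"c{i}" for i in range(2 * n)]
        act = _activity(np.ones((1, 2 * n)), cells)
        part = _partition(["GRN1"] * n + ["GRN2"] * n, cells)
        rss = g.regulon_specificity(act, part).set_index(["regulon", "grn"])["rss"]
        p = np.full(2 * n, 1 / (2 * n))
        q = np.concatenate([np.full(n, 1 / n), np.zeros(n)])
        expected = 1 - np.sqrt(jsd_summation(p, q))
        assert rss[("R0", "GRN1")] == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, small_activity, small_cohort):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=5, seed=0)
        rss1 = g.regulon_specificity(small_activity, part)
        scaled = ActivityMatrix(np.clip(small_activity.values * 0.37, 0, 1),
                                small_activity.regulon_ids,
                                small_activity.cell_ids, params={})
        rss2 = g.regulon_specificity(scaled, part)
        np.testing.assert_allclose(rss1["rss"], rss2["rss"], atol=1e-12)

    def test_zero_activity_regulon_missing(self):
        cells = [f"c{i}" for i in range(4)]
        act = _activity(np.array([[0, 0, 0, 0.0], [1, 0, 0, 0]]), cells)
        part = _partition(["GRN1", "GRN1", "GRN2", "GRN2"], cells)
        with pytest.warns(UserWarning, match="R0"):
            rss = g.regulon_specificity(act, part)
        assert rss.loc[rss.regulon == "R0", "rss"].isna().all()


class TestAssignRegulons:
    def test_planted_regulons_rank_first(self, small_activity, small_cohort):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=10, seed=0)
        rss = g.regulon_specificity(small_activity, part)
        ranked = g.assign_regulons(rss, small_activity, part, n_perm=200, seed=0)
        truth = small_cohort["truth"].state_of_cell
        for state in ("S1", "S2", "S3"):
            cells = truth[truth == state].index
            grn = part.labels.loc[cells].mode().iloc[0]
            top = ranked[(ranked.grn == grn) & (ranked["rank"] == 1)]
            assert top["regulon"].iloc[0] == state
            assert top["p_adj"].iloc[0] < 0.05

    def test_null_activity_calibration(self, rng):
        """Label-permutation p-values are uniform under exchangeable activity."""
        n_cells, n_regs = 60, 12
        cells = [f"c{i}" for i in range(n_cells)]
        act = _activity(rng.uniform(0, 1, size=(n_regs, n_cells)), cells)
        part = _partition(rng.choice(["GRN1", "GRN2"], n_cells), cells)
        rss = g.regulon_specificity(act, part)
        ranked = g.assign_regulons(rss, act, part, n_perm=400, seed=1)
        frac = (ranked["p_adj"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(ranked))
        assert frac <= 0.05 + 2 * se + 1e-9

    def test_adjusted_p_not_below_raw(self, small_activity):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=5, seed=0)
        rss = g.regulon_specificity(small_activity, part)
        ranked = g.assign_regulons(rss, small_activity, part, n_perm=150, seed=0)
        assert (ranked["p_adj"] >= ranked["p"] - 1e-12).all()

    def test_low_n_perm_warns(self, small_activity):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=5, seed=0)
        rss = g.regulon_specificity(small_activity, part)
        with pytest.warns(UserWarning, match="resolution"):
            g.assign_regulons(rss, small_activity, part, n_perm=50, seed=0)


class TestHoldoutRobustness:
    def test_multi_patient_states_are_stable(self, small_activity, small_cohort):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=10, seed=0)
        patients = small_cohort["truth"].patient_of_cell
        aris = g.holdout_robustness(small_activity, part, patients)
        assert (aris > 0.8).all()

    def test_single_unit_rejected(self, small_activity, small_cohort):
        part = g.select_cut_by_ari(small_activity, k_range=range(2, 6),
                                   n_resamples=5, seed=0)
        one = pd.Series("only", index=small_activity.cell_ids)
        with pytest.raises(ValidationError):
            g.holdout_robustness(small_activity, part, one)


class TestMarkerSummary:
    def test_single_grn_gene_scales_to_indicator(self, small_cohort, small_lognorm):
        truth = small_cohort["truth"].state_of_cell
        part = _partition([f"GRN{int(s[1])}" for s in truth], list(truth.index))
        gene = sorted(small_cohort["regulons"]["S1"].targets)[0]
        out = g.grn_marker_summary(small_lognorm, part, [gene])
        scaled = out["table"].set_index("grn")["scaled"]
        assert scaled["GRN1"] == pytest.approx(1.0)
        assert scaled[["GRN2", "GRN3"]].max() < 0.5

    def test_scaled_attains_zero_and_one(self, small_cohort, small_lognorm):
        truth = small_cohort["truth"].state_of_cell
        part = _partition([f"GRN{int(s[1])}" for s in truth], list(truth.index))
        genes = [sorted(small_cohort["regulons"][s].targets)[0] for s in ("S1", "S2")]
        out = g.grn_marker_summary(small_lognorm, part, genes)
        for gene in genes:
            v = out["table"].loc[out["table"].gene == gene, "scaled"]
            assert v.min() == 0.0 and v.max() == 1.0

    def test_constant_gene_warns_and_zeroes(self, small_cohort, small_lognorm):
        truth = small_cohort["truth"].state_of_cell
        part = _partition([f"GRN{int(s[1])}" for s in truth], list(truth.index))
        vals = small_lognorm.values.copy()
        vals[0] = 1.0
        em = g.ExpressionMatrix(vals, small_lognorm.gene_ids, small_lognorm.cell_ids,
                                layer="lognorm")
        with pytest.warns(UserWarning, match="constant"):
            out = g.grn_marker_summary(em, part, [em.gene_ids[0]])
        assert (out["table"]["scaled"] == 0).all()

    def test_planted_antigen_tracks_module(self):
        spec = g.CohortSimSpec(
            n_states=4, cells_per_state=80, genes_per_regulon=10,
            n_background_genes=80, baseline_mean=3.0,
            antigen_coupling=[("PSMA", "S1", 8.0)], seed=23,
        )
        em, _, regs, truth = g.simulate_cohort(spec)
        ln = g.lognormalize(em)
        part = _partition([f"GRN{int(s[1])}" for s in truth.state_of_cell],
                          list(truth.state_of_cell.index))
        out = g.grn_marker_summary(ln, part, ["PSMA"],
                                   module_sets={"S1_module": sorted(regs["S1"].targets)},
                                   seed=0)
        assoc = out["association"].set_index(["gene", "module"])
        assert assoc.loc[("PSMA", "S1_module"), "pearson_r"] > 0.8


class TestModelResults:
    def test_fit_returns_consistent_results(self, small_activity, small_cohort):
        res = g.GRNStateModel(small_activity).fit(k_range=range(2, 6),
                                                  n_resamples=8, n_perm=150, seed=0)
        assert res.n_grns == 3
        assert set(res.partition.labels.index) == set(small_activity.cell_ids)
        text = res.summary()
        assert "selected k (GRNs): 3" in text
        top = res.top_regulons("GRN1", 1)
        assert len(top) == 1

    def test_planted_activity_highest_in_own_state(self, small_activity, small_cohort):
        truth = small_cohort["truth"].state_of_cell
        vals = pd.DataFrame(small_activity.values, index=small_activity.regulon_ids,
                            columns=small_activity.cell_ids)
        for state in ("S1", "S2", "S3"):
            means = vals.loc[state].groupby(truth).mean()
            assert means.idxmax() == state
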