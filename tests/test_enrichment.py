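"""ΔΔCt fold changes, DEG calls, Fisher enrichment, set algebra,
correlations — including the bundled printed tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ap2erf.enrichment import (call_degs, cross_tissue_sets, ddct_fold_change,
                               fisher_from_counts, fisher_group_enrichment,
                               load_fixture, profile_correlation,
                               split_family_group)
from ap2erf.expression import CtTable, normalize


def two_stage_table(gene_stage_cts, replicates=3, noise=None, seed=0):
    """Ct table for one tissue with veraison/ripe stages."""
    rng = np.random.default_rng(seed)
    rows = []
    for stage in ("veraison", "ripe"):
        for rep in range(1, replicates + 1):
            for hk in ("HK1", "HK2", "HK3", "HK4"):
                rows.append((hk, "skin", stage, rep, 20.0))
            for g, cts in gene_stage_cts.items():
                ct = cts[stage]
                if noise:
                    ct = ct + rng.normal(0, noise)
                rows.append((g, "skin", stage, rep, ct))
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "stage",
                                     "replicate", "ct"])
    return CtTable(data=df, hk_genes=("HK1", "HK2", "HK3", "HK4"))


class TestDdct:
    def test_identical_stages_give_zero(self):
        ct = two_stage_table({"g1": {"veraison": 24.0, "ripe": 24.0}})
        fc = ddct_fold_change(normalize(ct), "skin", "veraison", "ripe")
        assert fc.set_index("gene_id").loc["g1", "log2fc"] == pytest.approx(0.0)

    def test_planted_three_ct_shift_is_eightfold(self):
        # 3 fewer cycles at ripeness = 2^3 = 8-fold induction
        ct = two_stage_table({"g1": {"veraison": 27.0, "ripe": 24.0}})
        fc = ddct_fold_change(normalize(ct), "skin", "veraison", "ripe")
        row = fc.set_index("gene_id").loc["g1"]
        assert row["log2fc"] == pytest.approx(3.0)
        assert row["sd"] == pytest.approx(0.0)

    def test_antisymmetry(self):
        ct = two_stage_table({"g1": {"veraison": 26.0, "ripe": 23.5}})
        rel = normalize(ct)
        fwd = ddct_fold_change(rel, "skin", "veraison", "ripe")
        rev = ddct_fold_change(rel, "skin", "ripe", "veraison")
        assert fwd.set_index("gene_id").loc["g1", "log2fc"] == pytest.approx(
            -rev.set_index("gene_id").loc["g1", "log2fc"])

    def test_gene_missing_one_stage_gets_reason(self):
        ct = two_stage_table({"g1": {"veraison": 24.0, "ripe": np.nan}})
        fc = ddct_fold_change(normalize(ct), "skin", "veraison", "ripe")
        row = fc.set_index("gene_id").loc["g1"]
        assert math.isnan(row["log2fc"])
        assert "ripe" in row["reason"]

    def test_missing_stage_rejected(self):
        ct = two_stage_table({"g1": {"veraison": 24.0, "ripe": 24.0}})
        with pytest.raises(ValueError, match="stages"):
            ddct_fold_change(normalize(ct), "skin", "veraison", "overripe")


class TestCallDegs:
    @pytest.mark.parametrize("log2fc,direction", [
        (2.03, "up"), (-2.09, "down"), (1.99, "unchanged"),
        (2.0, "up"), (-2.0, "down"), (0.0, "unchanged")])
    def test_threshold_partition(self, log2fc, direction):
        df = pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc],
                           "sd": [0.5]})
        assert call_degs(df)["direction"].iloc[0] == direction

    def test_sorted_by_descending_magnitude(self):
        df = pd.DataFrame({"gene_id": list("abcd"),
                           "log2fc": [1.0, -5.0, 3.0, -2.5],
                           "sd": [0.1] * 4})
        out = call_degs(df)
        assert out["gene_id"].tolist() == ["b", "c", "d", "a"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)],
                           "log2fc": rng.normal(0, 3, 50), "sd": 0.5})
        prev = None
        for thr in (1.0, 2.0, 3.0, 4.0):
            degs = call_degs(df, thr)
            called = set(degs.loc[degs["direction"] != "unchanged", "gene_id"])
            if prev is not None:
                assert called <= prev
            prev = called

    def test_single_replicate_flagged_low_confidence(self):
        df = pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [3.0, 2.5],
                           "sd": [np.nan, 0.4]})
        out = call_degs(df).set_index("gene_id")
        assert bool(out.loc["a", "low_confidence"]) is True
        assert bool(out.loc["b", "low_confidence"]) is False


class TestFisher:
    def test_small_case_matches_enumeration(self):
        # N=6, K=3, n=2, k=2: C(3,2)/C(6,2) = 3/15
        assert fisher_from_counts(2, 2, 3, 6) == pytest.approx(3 / 15)

    def test_saturated_tail_is_one(self):
        assert fisher_from_counts(3, 6, 3, 6) == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 6), (12, 4, 7)])
    def test_exhaustive_enumeration_oracle(self, N, K, n):
        """P(X >= k) equals direct enumeration over all C(N, n) draws."""
        universe = list(range(N))
        in_group = set(range(K))
        for k in range(min(n, K) + 1):
            count = sum(1 for draw in itertools.combinations(universe, n)
                        if len(in_group & set(draw)) >= k)
            expected = count / math.comb(N, n)
            assert fisher_from_counts(k, n, K, N) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_from_counts(5, 4, 10, 20)

    def test_group_table_background_from_catalogue(self):
        groups = pd.Series({"g1": "IX", "g2": "IX", "g3": "III",
                            "g4": "III", "g5": "IX", "g6": "I"})
        res = fisher_group_enrichment(["g1", "g2", "g5"], groups)
        ix = res.set_index("group").loc["IX"]
        assert ix["k"] == 3 and ix["K"] == 3 and ix["N"] == 6
        assert ix["p"] == pytest.approx(1 / math.comb(6, 3))

    def test_planted_enrichment_power(self):
        """With half the 30 planted DEGs drawn from a group holding ~25%
        of a 149-gene catalogue, the one-sided test flags the group at
        p <= 0.05 in at least 80% of seeded simulations."""
        from ap2erf.simulate import SimConfig, plant_deg_truth, vitis_like_universe
        cfg = SimConfig()
        uni = vitis_like_universe(cfg)
        groups = uni.set_index("gene_id")["group"]
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            planted = plant_deg_truth(cfg, uni, rng)
            res = fisher_group_enrichment(list(planted), groups)
            p = res.set_index("group").loc["IX", "p"]
            hits += p <= 0.05
        assert hits >= 0.8 * n_sims


class TestSets:
    def test_disjoint_lists(self):
        out = cross_tissue_sets({"a": ["x", "y"], "b": ["z"]})
        assert out["pairs"]["a&b"]["intersection"] == []

    def test_exact_name_matching_is_case_sensitive(self):
        out = cross_tissue_sets({"a": ["VvERF94"], "b": ["VvERF094"]})
        assert out["pairs"]["a&b"]["intersection"] == []

    def test_single_list_rejected(self):
        with pytest.raises(ValueError):
            cross_tissue_sets({"a": ["x"]})


class TestCorrelation:
    def test_identity_is_one(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert profile_correlation(x, x, "spearman") == pytest.approx(1.0)
        assert profile_correlation(x, x, "pearson") == pytest.approx(1.0)

    def test_monotone_transform_rank_invariance(self):
        x = np.linspace(1, 5, 8)
        y = np.exp(x)
        assert profile_correlation(x, y, "spearman") == pytest.approx(1.0)
        assert profile_correlation(x, y, "pearson") < 1.0

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        expected = (np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2)))
        assert profile_correlation(x, y, "pearson") == pytest.approx(expected)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            profile_correlation([1, 2, np.nan], [1, 2, 3])


class TestPrintedTables:
    """The transcribed skin/flesh tables behave as the publication states."""

    def test_skin_deg_counts(self):
        degs = call_degs(load_fixture("table2_skin"))
        assert (degs["direction"] == "up").sum() == 31
        assert (degs["direction"] == "down").sum() == 18

    def test_flesh_deg_counts(self):
        degs = call_degs(load_fixture("table3_flesh"))
        assert (degs["direction"] == "up").sum() == 18
        assert (degs["direction"] == "down").sum() == 30

    def test_cross_tissue_intersections(self):
        skin = call_degs(load_fixture("table2_skin"))
        flesh = call_degs(load_fixture("table3_flesh"))
        up = cross_tissue_sets({
            "skin": skin.loc[skin["direction"] == "up", "gene_id"],
            "flesh": flesh.loc[flesh["direction"] == "up", "gene_id"]})
        assert up["pairs"]["skin&flesh"]["intersection"] == \
            ["VvAP2-3", "VvERF072", "VvERF103"]
        down = cross_tissue_sets({
            "skin": skin.loc[skin["direction"] == "down", "gene_id"],
            "flesh": flesh.loc[flesh["direction"] == "down", "gene_id"]})
        assert down["pairs"]["skin&flesh"]["intersection"] == ["VvERF018"]

    def test_group_ix_overrepresented_in_skin_up(self):
        skin = call_degs(load_fixture("table2_skin"))
        fg = split_family_group(skin["family_group"])
        up = skin["direction"] == "up"
        k = int((up & (fg["group"] == "IX")).sum())
        counts = load_fixture("table1_counts")
        K = int(counts.query("family == 'ERF' and group == 'IX'")["vitis"].iloc[0])
        N = int(counts["vitis"].sum())
        p = fisher_from_counts(k, int(up.sum()), K, N)
        assert p <= 0.05

    def test_table1_totals(self):
        counts = load_fixture("table1_counts")
        assert counts["vitis"].sum() == 149
        assert counts["arabidopsis"].sum() == 147
        assert counts.query("family == 'ERF'")["vitis"].sum() == 122
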