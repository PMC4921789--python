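import io
import math

import numpy as np
import pandas as pd
import pytest

from coexnet import coexpression as cx
from oracles import brute_force_edges


def table_from_pairs(pairs: dict) -> pd.DataFrame:
    genes = sorted({g for pair in pairs for g in pair})
    ct = pd.DataFrame(np.nan, index=genes, columns=genes)
    for (a, b), v in pairs.items():
        ct.loc[a, b] = ct.loc[b, a] = v
    return ct


FOUR_GENE = table_from_pairs({("g1", "g2"): 0.9, ("g1", "g3"): 0.8,
                              ("g1", "g4"): 0.2, ("g2", "g3"): 0.5,
                              ("g2", "g4"): 0.4, ("g3", "g4"): 0.3})


class TestPearson:
    def test_self_and_anti_correlation(self):
        x = [1.0, 2.0, 4.0, 3.0]
        assert cx.pearson_cc(x, x) == pytest.approx(1.0)
        assert cx.pearson_cc(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_printed_formula_value(self):
        assert cx.pearson_cc([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(
            0.9827, abs=1e-4)

    def test_constant_vector_undefined(self):
        with pytest.raises(cx.ConstantVectorError):
            cx.pearson_cc([1, 1, 1], [1, 2, 3])

    def test_fewer_than_three_complete_pairs(self):
        with pytest.raises(cx.InsufficientDataError):
            cx.pearson_cc([1, 2, np.nan], [1, 2, 3])


class TestCorrelationTable:
    def test_identical_rows_give_unit_correlation(self):
        m = pd.DataFrame([[1, 2, 3.0], [1, 2, 3.0]], index=["a", "b"])
        ct = cx.correlation_table(m)
        assert ct.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(ct.loc["a", "a"])

    def test_matches_per_pair_brute_force(self, small_matrix):
        ct = cx.correlation_table(small_matrix)
        genes = list(small_matrix.index)
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                expected = cx.pearson_cc(small_matrix.loc[gi],
                                         small_matrix.loc[gj])
                assert ct.loc[gi, gj] == pytest.approx(expected, abs=1e-12)
                assert ct.loc[gj, gi] == ct.loc[gi, gj]

    def test_constant_gene_has_no_defined_edges(self):
        m = pd.DataFrame([[1, 2, 3, 4.0], [5, 5, 5, 5.0], [2, 1, 4, 3.0]],
                         index=["a", "flat", "c"])
        ct = cx.correlation_table(m)
        assert ct.loc["flat"].isna().all()

    def test_requires_three_samples(self):
        with pytest.raises(ValueError):
            cx.correlation_table(pd.DataFrame([[1, 2.0]], index=["a"]))


class TestMutualRank:
    def test_reciprocal_best_partners(self):
        assert cx.mutual_rank(1, 1) == 1.0

    def test_geometric_mean(self):
        assert cx.mutual_rank(2, 3) == pytest.approx(math.sqrt(6), abs=1e-3)
        assert cx.mutual_rank(3, 2) == cx.mutual_rank(2, 3)

    @pytest.mark.parametrize("a,b", [(0, 1), (1, -1), (1.5, 2)])
    def test_invalid_ranks(self, a, b):
        with pytest.raises(ValueError):
            cx.mutual_rank(a, b)


class TestRankPartners:
    def test_descending_pcc_order(self):
        ranks = cx.rank_partners(FOUR_GENE, "g1", "+")
        assert ranks.to_dict() == {"g2": 1, "g3": 2, "g4": 3}

    def test_ties_break_by_partner_id(self):
        ct = table_from_pairs({("g1", "g2"): 0.5, ("g1", "g3"): 0.5})
        ranks = cx.rank_partners(ct, "g1", "+")
        assert ranks.to_dict() == {"g2": 1, "g3": 2}

    def test_no_negative_partners_gives_empty_list(self):
        assert len(cx.rank_partners(FOUR_GENE, "g1", "-")) == 0

    def test_unknown_gene(self):
        with pytest.raises(KeyError):
            cx.rank_partners(FOUR_GENE, "nope", "+")


class TestClassifyEdges:
    def test_top3_makes_all_six_edges_tier_one(self):
        edges = cx.classify_edges(FOUR_GENE, cx.TierConfig(top_n=3))
        assert len(edges) == 6
        assert (edges["tier"] == 1).all()
        mrs = dict(zip(zip(edges["gene_a"], edges["gene_b"]), edges["mr"]))
        expected = {("g1", "g2"): 1.0, ("g1", "g3"): math.sqrt(2),
                    ("g1", "g4"): 3.0, ("g2", "g3"): 2.0,
                    ("g2", "g4"): math.sqrt(3), ("g3", "g4"): math.sqrt(6)}
        for pair, mr in expected.items():
            assert mrs[pair] == pytest.approx(mr)

    def test_top1_union_rule(self):
        edges = cx.classify_edges(FOUR_GENE, cx.TierConfig(top_n=1))
        tier1 = {(r.gene_a, r.gene_b) for r in edges.itertuples()
                 if r.tier == 1}
        # rank-1 partners: g1<->g2 reciprocal, g3's best is g1, g4's is g2
        assert tier1 == {("g1", "g2"), ("g1", "g3"), ("g2", "g4")}

    def test_empty_table(self):
        ct = pd.DataFrame(dtype=float)
        assert len(cx.classify_edges(ct)) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_full_sort_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        m = pd.DataFrame(rng.normal(size=(n, 10)),
                         index=[f"g{i:02d}" for i in range(n)])
        ct = cx.correlation_table(m)
        got = {(r.gene_a, r.gene_b): (r.mr, r.sign, r.tier)
               for r in cx.classify_edges(ct).itertuples()}
        expected = brute_force_edges(ct)
        assert got.keys() == expected.keys()
        for pair, (mr, sign, tier) in expected.items():
            gmr, gsign, gtier = got[pair]
            assert gmr == pytest.approx(mr, abs=1e-9)
            assert (gsign, gtier) == (sign, tier)


@pytest.fixture(scope="module")
def edges(small_matrix):
    return cx.classify_edges(cx.correlation_table(small_matrix))


class TestEdgeProperties:

    def test_mr_squared_is_an_integer_rank_product(self, edges):
        assert (np.abs(edges["mr"] ** 2 - np.round(edges["mr"] ** 2))
                < 1e-9).all()
        assert (edges["mr"] >= 1.0).all()

    def test_tiers_partition_the_edge_set(self, edges):
        assert edges.duplicated(["gene_a", "gene_b", "sign"]).sum() == 0
        assert set(edges["tier"]) <= {1, 2, 3}

    def test_sign_consistency(self, edges):
        pos = edges[edges["sign"] == "positive"]
        neg = edges[edges["sign"] == "negative"]
        assert (pos["pcc"] > 0).all() and (neg["pcc"] < 0).all()

    def test_deterministic_byte_identical_output(self, small_matrix):
        bufs = []
        for _ in range(2):
            edges = cx.classify_edges(cx.correlation_table(small_matrix))
            buf = io.StringIO()
            cx.write_edge_table(edges, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestBuildNetwork:
    def test_planted_modules_fully_positively_connected(self, planted):
        cfg, m, ann, labels = planted
        edges, _ = cx.build_coexpression_network(m)
        pos = {(r.gene_a, r.gene_b) for r in edges.itertuples()
               if r.sign == "positive"}
        tier1_cross = 0
        for r in edges.itertuples():
            la, lb = labels[r.gene_a], labels[r.gene_b]
            if r.tier == 1 and la != lb and la >= 0 and lb >= 0:
                tier1_cross += 1
        for mod in range(cfg.n_modules):
            members = sorted(labels.index[labels == mod])
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    assert (a, b) in pos
        assert tier1_cross == 0

    def test_coverage_percentage_arithmetic(self):
        # the published network spans 21,494 of 33,032 genes = 65.1%
        assert round(100 * 21494 / 33032, 1) == 65.1

    def test_summary_counts_consistent(self, small_matrix):
        edges, summary = cx.build_coexpression_network(
            small_matrix, genome_size=33032)
        assert summary["n_edges"] == len(edges)
        assert summary["n_nodes"] <= summary["n_genes_in"]
        assert sum(summary["edges_by_tier"].values()) == len(edges)


class TestTierConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(top_n=0), dict(mr_level2=30, mr_level3=5), dict(min_abs_pcc=1.5),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            cx.TierConfig(**kwargs)

    def test_min_abs_pcc_floor_drops_weak_edges(self):
        edges = cx.classify_edges(FOUR_GENE, cx.TierConfig(min_abs_pcc=0.45))
        assert (edges["pcc"].abs() >= 0.45).all()
        assert len(edges) == 3
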