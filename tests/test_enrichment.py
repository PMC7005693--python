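from math import comb

import numpy as np
import pytest

from nichescreen import (
    GeneSet,
    GeneSetCollection,
    RankedList,
    enrichment_graph,
    gsea_preranked,
    ora,
    rank_by_log2fc,
    read_gmt,
    write_gmt,
)
from nichescreen.enrichment import _es_from_positions, es_running_sum, set_similarity


def ranked_from_scores(scores, prefix="g"):
    scores = np.asarray(scores, dtype=float)
    return RankedList([f"{prefix}{i}" for i in range(len(scores))], scores)


def naive_es(scores, hit_positions, weight=1.0):
    """Independent cumulative-walk oracle for the weighted KS statistic.

    The ES is the maximal-magnitude excursion of the running sum; an exact
    magnitude tie between the positive and negative extremes resolves to the
    positive one (the package's documented convention).
    """
    n = len(scores)
    hits = np.zeros(n, dtype=bool)
    hits[list(hit_positions)] = True
    w = np.abs(np.asarray(scores, float)) ** weight
    nr = w[hits].sum()
    running = 0.0
    walk = []
    for i in range(n):
        if hits[i]:
            running += w[i] / nr
        else:
            running -= 1.0 / (n - hits.sum())
        walk.append(running)
    hi = max(max(walk), 0.0)
    lo = min(min(walk), 0.0)
    return hi if hi >= -lo - 1e-9 else lo


class TestRanking:
    def test_hand_log2fc(self, matrix_factory):
        m = matrix_factory([[4, 4, 1, 1]], ["EPI", "EPI", "TE", "TE"], scale="normalised")
        ranked = rank_by_log2fc(m, "EPI", "TE")
        assert ranked.scores[0] == pytest.approx(np.log2(5 / 2))
        assert ranked.label == "EPI_vs_TE"

    def test_equal_means_score_zero(self, matrix_factory):
        m = matrix_factory([[3, 3]], ["EPI", "TE"], scale="normalised")
        assert rank_by_log2fc(m, "EPI", "TE").scores[0] == 0.0

    def test_swapping_lineages_negates_scores(self, matrix_factory):
        rng = np.random.default_rng(0)
        m = matrix_factory(rng.random((30, 8)) * 50, ["EPI"] * 4 + ["TE"] * 4, scale="normalised")
        fwd = rank_by_log2fc(m, "EPI", "TE")
        rev = rank_by_log2fc(m, "TE", "EPI")
        fwd_scores = dict(zip(fwd.genes, fwd.scores))
        rev_scores = dict(zip(rev.genes, rev.scores))
        for g in fwd.genes:
            assert fwd_scores[g] == pytest.approx(-rev_scores[g])

    def test_missing_lineage_errors(self, matrix_factory):
        m = matrix_factory([[1, 2]], ["EPI", "TE"], scale="normalised")
        with pytest.raises(ValueError, match="PE"):
            rank_by_log2fc(m, "EPI", "PE")


class TestEnrichmentScore:
    def test_hand_running_sum(self):
        # scores (4,3,2,1), set = ranks {1,4}: walk 0.8, 0.3, -0.2, 0.0
        ranked = ranked_from_scores([4, 3, 2, 1])
        profile = es_running_sum(ranked, {"g0", "g3"})
        np.testing.assert_allclose(profile, [0.8, 0.3, -0.2, 0.0], atol=1e-15)
        es, _ = _es_from_positions(np.array([[0, 3]]), np.abs(ranked.scores), 4)
        assert es[0] == pytest.approx(0.8)

    def test_top_gene_set_scores_one(self):
        ranked = ranked_from_scores([5, 4, 3, 2, 1])
        es, _ = _es_from_positions(np.array([[0]]), np.abs(ranked.scores), 5)
        assert es[0] == pytest.approx(1.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            m = int(rng.integers(1, n))
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            pos = np.sort(rng.choice(n, m, replace=False))
            es, _ = _es_from_positions(pos[None, :], np.abs(scores), n)
            assert es[0] == pytest.approx(naive_es(scores, pos), abs=1e-12)

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            m = int(rng.integers(1, n))
            pos = np.sort(rng.choice(n, m, replace=False))
            es, _ = _es_from_positions(pos[None, :], rng.random(n) + 0.01, n)
            assert abs(es[0]) <= 1.0 + 1e-12

    def test_full_list_set_errors(self):
        ranked = ranked_from_scores([3, 2, 1])
        coll = GeneSetCollection([GeneSet("ALL", "", ["g0", "g1", "g2"])])
        with pytest.raises(ValueError, match="entire"):
            gsea_preranked(ranked, coll, nperm=10, seed=0, min_size=1)


class TestGseaPreranked:
    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        ranked = ranked_from_scores(np.sort(rng.normal(0, 1, 100))[::-1])
        coll = GeneSetCollection(
            [GeneSet(f"S{i}", "", [f"g{j}" for j in rng.choice(100, 10, replace=False)])
             for i in range(4)]
        )
        a = gsea_preranked(ranked, coll, nperm=200, seed=5)
        b = gsea_preranked(ranked, coll, nperm=200, seed=5)
        assert a.equals(b)

    def test_p_floor_never_zero(self):
        # a maximally enriched set must report p >= 1/(nperm + 1), not 0
        scores = np.concatenate([np.full(5, 10.0), np.full(95, 0.01)])
        ranked = ranked_from_scores(scores)
        coll = GeneSetCollection([GeneSet("TOP", "", [f"g{i}" for i in range(5)])])
        res = gsea_preranked(ranked, coll, nperm=100, seed=0)
        assert res["p_nominal"].iloc[0] >= 1.0 / 101

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(14)
        ranked = ranked_from_scores(np.sort(rng.normal(0, 1, 60))[::-1])
        members = [f"g{j}" for j in rng.choice(60, 12, replace=False)]
        coll = GeneSetCollection([GeneSet("S", "", members)])
        res = gsea_preranked(ranked, coll, nperm=100, seed=1)
        leading = res["leading_edge"].iloc[0].split(";")
        assert set(leading) <= set(members)
        assert 0 < len(leading) <= 12

    def test_sets_outside_size_window_skipped(self):
        ranked = ranked_from_scores(np.linspace(5, 0.1, 50))
        coll = GeneSetCollection(
            [
                GeneSet("TINY", "", ["g0", "g1"]),
                GeneSet("OK", "", [f"g{i}" for i in range(5, 15)]),
                GeneSet("MISSING", "", ["absent1", "absent2"]),
            ]
        )
        res = gsea_preranked(ranked, coll, nperm=50, seed=0, min_size=5)
        assert res["name"].tolist() == ["OK"]

    def test_bh_fdr_flag(self):
        rng = np.random.default_rng(15)
        ranked = ranked_from_scores(np.sort(rng.normal(0, 1, 80))[::-1])
        coll = GeneSetCollection(
            [GeneSet(f"S{i}", "", [f"g{j}" for j in rng.choice(80, 8, replace=False)])
             for i in range(5)]
        )
        res = gsea_preranked(ranked, coll, nperm=100, seed=2, fdr_method="bh")
        assert ((res["fdr_q"] >= res["p_nominal"]) | res["fdr_q"].isna()).all()


class TestOra:
    def test_hand_full_overlap(self):
        coll = GeneSetCollection([GeneSet("S", "", [f"u{i}" for i in range(5)])])
        universe = [f"u{i}" for i in range(20)]
        res = ora([f"u{i}" for i in range(5)], coll, universe)
        assert res["p_hyper"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_is_one(self):
        coll = GeneSetCollection([GeneSet("S", "", ["u0", "u1"])])
        res = ora(["u5", "u6"], coll, [f"u{i}" for i in range(10)])
        assert res["p_hyper"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(16)
        for _ in range(50):
            m_total = int(rng.integers(4, 26))
            universe = [f"u{i}" for i in range(m_total)]
            n_query = int(rng.integers(1, m_total + 1))
            k_set = int(rng.integers(1, m_total + 1))
            query = list(rng.choice(universe, n_query, replace=False))
            members = list(rng.choice(universe, k_set, replace=False))
            res = ora(query, GeneSetCollection([GeneSet("S", "", members)]), universe)
            k = len(set(query) & set(members))
            expected = sum(
                comb(k_set, j) * comb(m_total - k_set, n_query - j)
                for j in range(k, min(k_set, n_query) + 1)
                if n_query - j <= m_total - k_set
            ) / comb(m_total, n_query)
            assert res["p_hyper"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_query_outside_universe_errors(self):
        coll = GeneSetCollection([GeneSet("S", "", ["u0"])])
        with pytest.raises(ValueError, match="outside"):
            ora(["stranger"], coll, ["u0", "u1"])

    def test_empty_inputs_error(self):
        coll = GeneSetCollection([GeneSet("S", "", ["u0"])])
        with pytest.raises(ValueError):
            ora([], coll, ["u0"])
        with pytest.raises(ValueError):
            ora(["u0"], coll, [])


class TestSimilarityGraph:
    def test_hand_jaccard_overlap(self):
        jac, ovl = set_similarity({"A", "B", "C"}, {"B", "C", "D"})
        assert jac == pytest.approx(0.5)
        assert ovl == pytest.approx(2 / 3)

    def test_identical_and_disjoint(self):
        assert set_similarity({"A"}, {"A"}) == (1.0, 1.0)
        assert set_similarity({"A"}, {"B"}) == (0.0, 0.0)

    def test_graph_filters_by_p_and_similarity(self):
        import pandas as pd

        results = pd.DataFrame(
            {
                "name": ["S1", "S2", "S3"],
                "size": [3, 3, 3],
                "es": [0.9, 0.8, 0.5],
                "nes": [2.0, 1.9, 1.0],
                "p_nominal": [0.01, 0.02, 0.5],
                "fdr_q": [0.05, 0.05, 0.9],
                "n_hits": [3, 3, 3],
                "leading_edge": ["", "", ""],
            }
        )
        coll = GeneSetCollection(
            [
                GeneSet("S1", "", ["A", "B", "C"]),
                GeneSet("S2", "", ["B", "C", "D"]),
                GeneSet("S3", "", ["X", "Y", "Z"]),
            ]
        )
        graph = enrichment_graph(results, coll, p_cutoff=0.05, similarity_cutoff=0.5)
        assert set(graph.nodes) == {"S1", "S2"}
        assert graph.has_edge("S1", "S2")
        assert graph.edges["S1", "S2"]["jaccard"] == pytest.approx(0.5)


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            [GeneSet("S1", "first", ["A", "B"]), GeneSet("S2", "second", ["C"])]
        )
        write_gmt(coll, tmp_path / "sets.gmt")
        back = read_gmt(tmp_path / "sets.gmt")
        assert back.names() == ["S1", "S2"]
        assert back.get("S1").genes == ["A", "B"]

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneSetCollection([GeneSet("S", "", ["A"]), GeneSet("S", "", ["B"])])
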