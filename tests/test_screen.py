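from itertools import product

import numpy as np
import pandas as pd
import pytest

from nichescreen import (
    LineageMedianTable,
    ScaleError,
    call_interactions,
    load_catalogue,
    load_ppi,
    pair_by_ppi,
    rank_interactions,
)
from nichescreen.expression import FormatError
from nichescreen.screen import LRCatalogue, PPITable


def median_table(data: dict, lineages=("EPI", "PE", "TE"), scale="rpkm"):
    return LineageMedianTable(
        pd.DataFrame.from_dict(data, orient="index", columns=list(lineages)), scale
    )


IGF_MEDIANS = median_table({"IGF1": [1, 20, 1], "IGF1R": [12, 3, 2]})


class TestLoaders:
    def test_catalogue_roles_and_counts(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text(
            "gene\trole\tpathways\n"
            "IGF1\tligand\thsa04151\n"
            "IGF1R\treceptor\thsa04151\n"
            "INSR\treceptor\thsa04910\n"
        )
        cat = load_catalogue(path)
        assert cat.ligands == {"IGF1"}
        assert cat.receptors == {"IGF1R", "INSR"}

    def test_duplicate_rows_collapse(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("IGF1\tligand\ta\nIGF1\tligand\tb\n")
        cat = load_catalogue(path)
        assert len(cat) == 1
        assert cat.entries.iloc[0]["pathways"] == "a;b"

    def test_unknown_role_reports_line_number(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("IGF1\tligand\n" "FOO\tenzyme\n")
        with pytest.raises(FormatError, match=":2"):
            load_catalogue(path)

    def test_ppi_both_directions_collapse(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("IGF1\tIGF1R\t0.9\nIGF1R\tIGF1\t0.7\n")
        ppi = load_ppi(path)
        assert len(ppi) == 1
        assert ppi.edge_set()[("IGF1", "IGF1R")] == 0.9

    def test_ppi_hippie_dialect(self, tmp_path):
        path = tmp_path / "hippie.tsv"
        path.write_text(
            "IGF1_HUMAN\t3479\tIGF1R_HUMAN\t3480\t0.96\texperiments:in vivo\n"
            "INS_HUMAN\t3630\tINSR_HUMAN\t3643\t0.92\texperiments:in vitro\n"
        )
        ppi = load_ppi(path)
        assert ppi.edge_set() == {("IGF1", "IGF1R"): 0.96, ("INS", "INSR"): 0.92}

    def test_ppi_missing_confidence_defaults_to_one(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\n")
        assert load_ppi(path).edge_set()[("A", "B")] == 1.0

    def test_ppi_confidence_out_of_range(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\t1.5\n")
        with pytest.raises(FormatError, match="1.5"):
            load_ppi(path)


def brute_force_pairs(ligands, receptors, edges, min_confidence=0.0):
    """Cross-product filter oracle for pairing."""
    found = set()
    for lig, rec in product(sorted(ligands), sorted(receptors)):
        if lig == rec:
            continue
        key = tuple(sorted((lig, rec)))
        if key in edges and edges[key] >= min_confidence:
            found.add((lig, rec))
    return found


def random_instance(rng, n_genes=None):
    n = int(rng.integers(2, 21)) if n_genes is None else n_genes
    genes = [f"g{i}" for i in range(n)]
    roles = []
    for g in genes:
        r = rng.random()
        if r < 0.4:
            roles.append((g, "ligand"))
        elif r < 0.8:
            roles.append((g, "receptor"))
        else:  # dual role
            roles.append((g, "ligand"))
            roles.append((g, "receptor"))
    cat = LRCatalogue(pd.DataFrame([{"gene": g, "role": r, "pathways": ""} for g, r in roles]))
    n_edges = int(rng.integers(0, n * 2 + 1))
    edges = {}
    for _ in range(n_edges):
        a, b = rng.choice(genes, 2, replace=False)
        edges[tuple(sorted((a, b)))] = float(np.round(rng.random(), 3))
    ppi = PPITable(
        pd.DataFrame(
            [{"gene_a": a, "gene_b": b, "confidence": c} for (a, b), c in sorted(edges.items())],
            columns=["gene_a", "gene_b", "confidence"],
        )
    )
    return cat, ppi, edges


class TestPairing:
    def test_simple_pairing(self):
        cat = LRCatalogue(
            pd.DataFrame(
                [
                    {"gene": "L1", "role": "ligand", "pathways": ""},
                    {"gene": "R1", "role": "receptor", "pathways": ""},
                    {"gene": "R2", "role": "receptor", "pathways": ""},
                ]
            )
        )
        ppi = PPITable(pd.DataFrame([{"gene_a": "L1", "gene_b": "R1", "confidence": 1.0}]))
        pairs = pair_by_ppi(cat, ppi)
        assert list(map(tuple, pairs[["ligand", "receptor"]].to_numpy())) == [("L1", "R1")]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cat, ppi, edges = random_instance(rng)
            min_conf = float(rng.choice([0.0, 0.3, 0.7]))
            got = set(map(tuple, pair_by_ppi(cat, ppi, min_conf)[["ligand", "receptor"]].to_numpy()))
            assert got == brute_force_pairs(cat.ligands, cat.receptors, edges, min_conf)

    def test_raising_confidence_never_adds_pairs(self):
        rng = np.random.default_rng(8)
        cat, ppi, _ = random_instance(rng, n_genes=15)
        previous = None
        for min_conf in (0.0, 0.25, 0.5, 0.75, 1.0):
            got = set(map(tuple, pair_by_ppi(cat, ppi, min_conf)[["ligand", "receptor"]].to_numpy()))
            if previous is not None:
                assert got <= previous
            previous = got


class TestCallInteractions:
    def test_igf_motif_single_paracrine_call(self):
        pairs = pd.DataFrame([{"ligand": "IGF1", "receptor": "IGF1R", "confidence": 1.0}])
        calls = call_interactions(pairs, IGF_MEDIANS, 5.0)
        assert len(calls) == 1
        call = calls[0]
        assert (call.source_lineage, call.target_lineage) == ("PE", "EPI")
        assert call.interaction_class == "paracrine"

    def test_all_zero_medians_no_calls(self):
        pairs = pd.DataFrame([{"ligand": "IGF1", "receptor": "IGF1R", "confidence": 1.0}])
        med = median_table({"IGF1": [0, 0, 0], "IGF1R": [0, 0, 0]})
        assert call_interactions(pairs, med, 5.0) == []

    def test_threshold_boundary_inclusive(self):
        pairs = pd.DataFrame([{"ligand": "L", "receptor": "R", "confidence": 1.0}])
        med = median_table({"L": [5.0, 0, 0], "R": [5.0, 0, 0]})
        assert len(call_interactions(pairs, med, 5.0)) == 1
        assert len(call_interactions(pairs, med, 5.0, inclusive=False)) == 0

    def test_raising_threshold_never_adds_calls(self):
        pairs = pd.DataFrame([{"ligand": "IGF1", "receptor": "IGF1R", "confidence": 1.0}])
        previous = None
        for tau in (0.0, 2.0, 5.0, 13.0, 25.0):
            ids = {
                (c.source_lineage, c.target_lineage)
                for c in call_interactions(pairs, IGF_MEDIANS, tau)
            }
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_requires_rpkm_medians(self):
        pairs = pd.DataFrame([{"ligand": "L", "receptor": "R", "confidence": 1.0}])
        med = median_table({"L": [9, 0, 0], "R": [9, 0, 0]}, scale="log2")
        with pytest.raises(ScaleError):
            call_interactions(pairs, med, 5.0)

    def test_missing_gene_skipped_with_warning(self, caplog):
        pairs = pd.DataFrame([{"ligand": "NOPE", "receptor": "IGF1R", "confidence": 1.0}])
        with caplog.at_level("WARNING"):
            assert call_interactions(pairs, IGF_MEDIANS, 5.0) == []
        assert any("NOPE" in r.message for r in caplog.records)

    def test_lineage_permutation_symmetry(self):
        pairs = pd.DataFrame([{"ligand": "IGF1", "receptor": "IGF1R", "confidence": 1.0}])
        permuted = LineageMedianTable(IGF_MEDIANS.values[["TE", "EPI", "PE"]], "rpkm")
        a = {(c.source_lineage, c.target_lineage) for c in call_interactions(pairs, IGF_MEDIANS)}
        b = {(c.source_lineage, c.target_lineage) for c in call_interactions(pairs, permuted)}
        assert a == b == {("PE", "EPI")}


class TestRanking:
    def test_hand_specificity_score(self):
        pairs = pd.DataFrame([{"ligand": "IGF1", "receptor": "IGF1R", "confidence": 1.0}])
        calls = rank_interactions(call_interactions(pairs, IGF_MEDIANS, 5.0), IGF_MEDIANS)
        # min(fold(IGF1, PE), fold(IGF1R, EPI)) = min(21/2, 13/4) = 3.25
        assert calls[0].specificity_score == pytest.approx(3.25)

    def test_uniform_gene_has_unit_fold(self):
        med = median_table({"L": [7, 7, 7], "R": [7, 7, 7]})
        pairs = pd.DataFrame([{"ligand": "L", "receptor": "R", "confidence": 1.0}])
        calls = rank_interactions(call_interactions(pairs, med, 5.0), med)
        assert all(c.specificity_score == pytest.approx(1.0) for c in calls)

    def test_ties_break_lexicographically(self):
        med = median_table({"LA": [9, 0, 0], "LB": [9, 0, 0], "R": [9, 9, 9]})
        pairs = pd.DataFrame(
            [
                {"ligand": "LB", "receptor": "R", "confidence": 1.0},
                {"ligand": "LA", "receptor": "R", "confidence": 1.0},
            ]
        )
        calls = rank_interactions(call_interactions(pairs, med, 5.0), med)
        scores = [c.specificity_score for c in calls]
        assert scores == sorted(scores, reverse=True)
        tied = [(c.ligand, c.receptor) for c in calls if c.specificity_score == scores[0]]
        assert tied == sorted(tied)

    def test_single_lineage_errors(self):
        med = LineageMedianTable(pd.DataFrame({"EPI": [9, 9]}, index=["L", "R"]), "rpkm")
        pairs = pd.DataFrame([{"ligand": "L", "receptor": "R", "confidence": 1.0}])
        calls = call_interactions(pairs, med, 5.0)
        with pytest.raises(ValueError, match="two lineages"):
            rank_interactions(calls, med)
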