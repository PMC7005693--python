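"""End-to-end orchestration: simulate -> normalise -> screen -> enrich -> overlay.

Every stage writes its outputs under the configured directory with stable,
schema-versioned filenames, and the run report records per-stage record
counts, the full parameter echo and the seed. Given an identical
configuration (seed included) two runs produce byte-identical artefacts; the
single seed is fanned out to the stochastic stages through fixed offsets so
each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .enrichment import (
    GeneSetCollection,
    enrichment_graph,
    gsea_preranked,
    ora,
    rank_by_log2fc,
    read_gmt,
    write_gmt,
    write_graph,
)
from .expression import (
    log2p1,
    lineage_medians,
    normalise_by_size_factors,
    read_gene_lengths,
    read_matrix,
    rpkm,
    size_factors,
    write_gene_lengths,
    write_matrix,
)
from .hvg import select_hvgs
from .overlay import PathwayGraph, PathwayNode, colour_nodes, export_overlay, load_pathway
from .screen import (
    call_interactions,
    load_catalogue,
    load_ppi,
    pair_by_ppi,
    rank_interactions,
    write_calls,
)
from .simulate import build_toy_catalogue, build_toy_genesets, simulate_dataset

logger = logging.getLogger(__name__)

_SEED_MODULUS = 2**31


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def _stage_seed(seed: int, offset: int) -> int:
    return (seed + offset) % _SEED_MODULUS


def _toy_pathway_from_truth(truth) -> PathwayGraph:
    """A small signalling diagram wired from the planted circuits: each
    ligand points at its receptor, and all receptors feed one downstream
    category node (plus a non-gene node standing in for a compound)."""
    nodes: dict[str, PathwayNode] = {}
    edges = []
    receptors = []
    for lig, rec, _src, _tgt in truth.true_interactions:
        nodes[f"n_{lig}"] = PathwayNode(f"n_{lig}", lig, [lig], "gene_product")
        nodes[f"n_{rec}"] = PathwayNode(f"n_{rec}", rec, [rec], "gene_product")
        edges.append((f"n_{lig}", f"n_{rec}", "activation"))
        receptors.append(rec)
    if len(receptors) >= 2:
        nodes["n_receptors"] = PathwayNode(
            "n_receptors", "receptor_module", sorted(set(receptors)), "category"
        )
    nodes["n_signal"] = PathwayNode("n_signal", "second_messenger", [], "non_gene")
    if receptors:
        edges.append((f"n_{receptors[0]}", "n_signal", "activation"))
    graph = PathwayGraph("toy_niche_signalling", "Planted niche signalling", nodes, edges)
    graph.validate()
    return graph


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report (also serialised to JSON)."""
    diagnostics = config.validate()
    if diagnostics:
        raise PipelineError("config: " + "; ".join(diagnostics))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": json.loads(json.dumps(dataclasses.asdict(config), default=list)),
        "stages": [],
    }
    current = "setup"

    def record(stage: str, n_records: int) -> None:
        logger.info("[%s] %d records", stage, n_records)
        report["stages"].append({"stage": stage, "n_records": n_records})

    try:
        # -- input / simulation -------------------------------------------
        current = "simulate"
        truth = None
        if config.matrix_path is None:
            sim = dataclasses.replace(config.simulation, seed=_stage_seed(config.seed, 0))
            counts, lengths, truth = simulate_dataset(sim)
            write_matrix(counts, out / "counts.tsv", out / "annotations.tsv")
            write_gene_lengths(lengths, out / "gene_lengths.tsv")
            truth.to_json(out / "ground_truth.json")
        else:
            counts = read_matrix(config.matrix_path, config.annotations_path, "counts")
            lengths = read_gene_lengths(config.gene_lengths_path)
        record("simulate", counts.n_genes * counts.n_cells)

        current = "catalogue"
        if config.catalogue_path is not None:
            catalogue = load_catalogue(config.catalogue_path)
            ppi = load_ppi(config.ppi_path)
        elif truth is not None:
            catalogue, ppi = build_toy_catalogue(truth, config.simulation)
            catalogue.to_tsv(out / "catalogue.tsv")
            ppi.to_tsv(out / "ppi.tsv")
        else:
            raise ValueError("no catalogue/ppi inputs and no simulated truth")
        record("catalogue", len(catalogue))

        # -- normalisation --------------------------------------------------
        current = "normalise"
        rpkm_matrix = rpkm(counts, lengths)
        medians = lineage_medians(rpkm_matrix)
        medians.to_tsv(out / "lineage_medians_rpkm.tsv")
        sf = size_factors(counts)
        sf.to_csv(out / "size_factors.tsv", sep="\t", index_label="cell_id")
        normalised = normalise_by_size_factors(counts)
        logged = log2p1(normalised)
        record("normalise", counts.n_cells)

        current = "hvg"
        hvg_table = select_hvgs(logged, alpha=config.hvg_alpha)
        hvg_table.to_csv(out / "hvg.tsv", sep="\t", index_label="gene")
        record("hvg", int(hvg_table["is_hvg"].sum()))

        # -- ligand-receptor screen ----------------------------------------
        current = "screen"
        pairs = pair_by_ppi(catalogue, ppi, config.min_confidence)
        calls = call_interactions(pairs, medians, config.expression_threshold)
        calls = rank_interactions(calls, medians, config.pseudocount)
        write_calls(calls, out / "interaction_calls.tsv")
        record("screen", len(calls))

        # -- enrichment -----------------------------------------------------
        current = "gsea"
        if config.genesets_path is not None:
            collection = read_gmt(config.genesets_path)
        elif truth is not None:
            collection = build_toy_genesets(truth, seed=_stage_seed(config.seed, 2))
            write_gmt(collection, out / "gene_sets.gmt")
        else:
            collection = GeneSetCollection([])
        ranked = rank_by_log2fc(normalised, *config.comparison, config.pseudocount)
        ranked.to_rnk(out / f"ranked_{ranked.label}.rnk")
        gsea_results = gsea_preranked(
            ranked,
            collection,
            weight=config.gsea_weight,
            nperm=config.nperm,
            seed=_stage_seed(config.seed, 1),
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
        )
        gsea_results.to_csv(out / "gsea_results.tsv", sep="\t", index=False)
        record("gsea", len(gsea_results))

        current = "enrichment_graph"
        graph = enrichment_graph(
            gsea_results, collection, config.gsea_p_cutoff, config.similarity_cutoff
        )
        write_graph(
            graph,
            out / "enrichment_map.graphml",
            out / "enrichment_map_nodes.tsv",
            out / "enrichment_map_edges.tsv",
        )
        record("enrichment_graph", graph.number_of_nodes())

        current = "ora"
        universe = list(map(str, counts.gene_ids))
        query = sorted(hvg_table.index[hvg_table["is_hvg"]].astype(str))
        if not query:  # fall back to the strongest-ranked genes
            query = list(ranked.genes[: max(10, len(ranked) // 100)])
        ora_results = ora(query, collection, universe) if len(collection) else None
        if ora_results is not None:
            ora_results.to_csv(out / "ora_results.tsv", sep="\t", index=False)
            record("ora", len(ora_results))

        # -- pathway overlay ------------------------------------------------
        current = "overlay"
        if config.pathway_path is not None:
            pathway = load_pathway(config.pathway_path)
        elif truth is not None and truth.true_interactions:
            pathway = _toy_pathway_from_truth(truth)
        else:
            pathway = None
        if pathway is not None:
            colourings = [
                colour_nodes(pathway, medians, ct, config.overlay_range, config.n_bins)
                for ct in medians.lineage_names
            ]
            export_overlay(
                pathway,
                colourings,
                rpkm_matrix,
                out / "pathway_overlay.graphml",
                out / "pathway_boxplots.json",
            )
            record("overlay", len(pathway.nodes))
    except Exception as exc:
        report["failed_stage"] = current
        report["error"] = str(exc)
        (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
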