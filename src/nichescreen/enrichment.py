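"""Preranked gene-set enrichment, over-representation, and the set-similarity graph.

Preranked GSEA: genes are ranked by pseudocounted mean-ratio log2 fold change
between two lineages; for each gene set a weighted Kolmogorov-Smirnov running
sum walks down the ranked list, adding |score|^p / NR at set members and
subtracting 1 / (N - |S|) elsewhere. The enrichment score (ES) is the
maximal-magnitude excursion of this walk. A null distribution from gene-label
permutations yields the nominal p-value, the normalised enrichment score
(NES = ES / mean |same-sign null ES|) and an empirical FDR computed over the
pooled null NES distribution.

Over-representation analysis (ORA) is the exact hypergeometric upper tail
with Benjamini-Hochberg correction across sets, and the similarity graph
links significantly enriched sets whose overlap coefficient reaches a cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Tolerance for resolving a positive/negative excursion-magnitude tie in the
#: enrichment score; exact ties occur (e.g. single-hit or near-complement
#: sets) and would otherwise flip sign on floating-point noise.
_ES_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dup}")
        for s in self.sets:
            if not s.genes:
                raise ValueError(f"gene set {s.name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def get(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


def read_gmt(path) -> GeneSetCollection:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT lines need name, description, members")
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedList:
    """Genes in strictly decreasing score order (ties broken by symbol)."""

    genes: list[str]
    scores: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list genes must be unique")
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.genes)

    def to_rnk(self, path) -> None:
        pd.DataFrame({"gene": self.genes, "score": self.scores}).to_csv(
            path, sep="\t", index=False, header=False
        )


def read_rnk(path, label: str = "") -> RankedList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
    order = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(order["gene"].astype(str).tolist(), order["score"].to_numpy(), label)


def rank_by_log2fc(
    matrix: ExpressionMatrix,
    lineage_a: str,
    lineage_b: str,
    pseudocount: float = 1.0,
) -> RankedList:
    """Rank all genes by log2((mean_a + psi) / (mean_b + psi)), descending.

    Swapping the lineages negates every score. Ties break by gene symbol so
    the ranking, and everything downstream of it, is reproducible.
    """
    matrix.require_scale("normalised")
    for lin in (lineage_a, lineage_b):
        if (matrix.annotations["lineage"] == lin).sum() == 0:
            raise ValueError(f"lineage {lin!r} absent from the matrix")
    mean_a = matrix.values[matrix.cells_of(lineage_a)].mean(axis=1)
    mean_b = matrix.values[matrix.cells_of(lineage_b)].mean(axis=1)
    score = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    df = pd.DataFrame({"gene": matrix.gene_ids.astype(str), "score": score.to_numpy()})
    df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(df["gene"].tolist(), df["score"].to_numpy(), f"{lineage_a}_vs_{lineage_b}")


# ---------------------------------------------------------------------------
# Enrichment score machinery
# ---------------------------------------------------------------------------

def _es_from_positions(positions: np.ndarray, hit_weights: np.ndarray, n_genes: int):
    """Vectorised enrichment scores from hit positions.

    Parameters
    ----------
    positions
        (P, m) integer array of 0-based hit positions, sorted row-wise.
    hit_weights
        |score|^p evaluated over the whole ranked list, length n_genes.
    n_genes
        Length of the ranked list N.

    Returns
    -------
    es : (P,) signed enrichment scores (maximal-magnitude excursion).
    peak_hit : (P,) index (into the m hits) of the extremum, for leading-edge
        extraction.
    """
    positions = np.atleast_2d(positions)
    n_perm, m = positions.shape
    if m >= n_genes:
        raise ValueError("gene set covers the whole ranked list; miss decrement undefined")
    w = hit_weights[positions]
    nr = w.sum(axis=1, keepdims=True)
    # all-zero weights (e.g. every member has score 0): fall back to equal steps
    degenerate = nr[:, 0] == 0
    if degenerate.any():
        w = np.where(degenerate[:, None], 1.0, w)
        nr = w.sum(axis=1, keepdims=True)
    cw = np.cumsum(w, axis=1) / nr
    k = np.arange(m)
    miss = 1.0 / (n_genes - m)
    n_misses_before = positions - k  # misses strictly before hit k
    peak = cw - n_misses_before * miss  # running sum just after hit k
    cw_prev = np.concatenate([np.zeros((n_perm, 1)), cw[:, :-1]], axis=1)
    trough = cw_prev - n_misses_before * miss  # running sum just before hit k
    max_run = peak.max(axis=1)
    min_run = np.minimum(trough.min(axis=1), 0.0)
    # magnitude ties (within fp noise) resolve to the positive excursion
    positive = max_run >= -min_run - _ES_TIE_TOL
    es = np.where(positive, max_run, min_run)
    peak_hit = np.where(positive, peak.argmax(axis=1), trough.argmin(axis=1))
    return es, peak_hit


def es_running_sum(ranked: RankedList, members, weight: float = 1.0) -> np.ndarray:
    """Full running-sum profile of the weighted KS walk (length N).

    Exposed mainly for inspection/plotting; the ES equals the entry of
    maximal magnitude.
    """
    n = len(ranked)
    hits = np.isin(np.asarray(ranked.genes, dtype=object), list(members))
    m = int(hits.sum())
    if m == 0 or m >= n:
        raise ValueError("set must hit a non-empty proper subset of the ranked list")
    w = np.abs(ranked.scores) ** weight
    steps = np.full(n, -1.0 / (n - m))
    hw = w[hits]
    total = hw.sum()
    steps[hits] = hw / total if total > 0 else 1.0 / m
    return np.cumsum(steps)


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    n_hits: int
    leading_edge: list[str]


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int | None = None,
    min_size: int = 5,
    max_size: int = 500,
    fdr_method: str = "pooled",
) -> pd.DataFrame:
    """Preranked GSEA over a collection of gene sets.

    The null distribution permutes set membership over gene labels ``nperm``
    times. Nominal p is the same-sign tail fraction with a +1 correction, so
    p is never reported as 0 (floor 1 / (nperm + 1)). ``fdr_method`` is
    either ``"pooled"`` (empirical FDR over the pooled null NES distribution)
    or ``"bh"`` (Benjamini-Hochberg on the nominal p-values).

    Returns a DataFrame with one row per retained set, in collection order.
    """
    if fdr_method not in ("pooled", "bh"):
        raise ValueError("fdr_method must be 'pooled' or 'bh'")
    n = len(ranked)
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    abs_w = np.abs(ranked.scores) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_pools: list[np.ndarray] = []
    for gene_set in collection:
        positions = np.array(sorted({gene_pos[g] for g in gene_set.genes if g in gene_pos}))
        m = len(positions)
        if m == 0:
            logger.warning("gene set %s has no members in the ranked list; skipped", gene_set.name)
            continue
        if m >= n:
            raise ValueError(f"gene set {gene_set.name!r} covers the entire ranked list")
        if not (min_size <= m <= max_size):
            logger.info("gene set %s (size %d) outside [%d, %d]; skipped",
                        gene_set.name, m, min_size, max_size)
            continue

        es_arr, peak_arr = _es_from_positions(positions[None, :], abs_w, n)
        es, peak_hit = float(es_arr[0]), int(peak_arr[0])

        null_pos = np.sort(
            np.argpartition(rng.random((nperm, n)), m, axis=1)[:, :m], axis=1
        )
        null_es, _ = _es_from_positions(null_pos, abs_w, n)

        pos_null = null_es[null_es >= 0]
        neg_null = null_es[null_es < 0]
        if es >= 0:
            p = (1 + int((pos_null >= es).sum())) / (1 + pos_null.size)
            nes = es / pos_null.mean() if pos_null.size else float("nan")
        else:
            p = (1 + int((neg_null <= es).sum())) / (1 + neg_null.size)
            nes = -(es / neg_null.mean()) if neg_null.size else float("nan")

        # null NES for the pooled-FDR convention: each null ES normalised by
        # the mean same-sign null magnitude of its own set
        pools = []
        if pos_null.size:
            pools.append(pos_null / pos_null.mean())
        if neg_null.size:
            pools.append(-(neg_null / neg_null.mean()))
        null_nes_pools.append(np.concatenate(pools) if pools else np.empty(0))

        if es >= 0:
            le_positions = positions[: peak_hit + 1]
        else:
            le_positions = positions[peak_hit:]
        leading_edge = [ranked.genes[i] for i in le_positions]

        rows.append(
            GseaResult(gene_set.name, m, es, float(nes), float(p), float("nan"), m, leading_edge)
        )

    result = pd.DataFrame(
        [
            {
                "name": r.name,
                "size": r.size,
                "es": r.es,
                "nes": r.nes,
                "p_nominal": r.p_nominal,
                "fdr_q": r.fdr_q,
                "n_hits": r.n_hits,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in rows
        ],
        columns=["name", "size", "es", "nes", "p_nominal", "fdr_q", "n_hits", "leading_edge"],
    )
    if not len(result):
        return result

    if fdr_method == "bh":
        result["fdr_q"] = multipletests(result["p_nominal"].to_numpy(), method="fdr_bh")[1]
        return result

    pooled = np.concatenate(null_nes_pools) if null_nes_pools else np.empty(0)
    obs = result["nes"].to_numpy()
    qs = np.empty(len(result))
    for i, nes_i in enumerate(obs):
        if not np.isfinite(nes_i):
            qs[i] = float("nan")
            continue
        if nes_i >= 0:
            null_tail = (pooled >= nes_i).sum()
            null_side = (pooled >= 0).sum()
            obs_tail = (obs >= nes_i).sum()
            obs_side = (obs >= 0).sum()
        else:
            null_tail = (pooled <= nes_i).sum()
            null_side = (pooled < 0).sum()
            obs_tail = (obs <= nes_i).sum()
            obs_side = (obs < 0).sum()
        if null_side == 0 or obs_tail == 0 or obs_side == 0:
            qs[i] = 1.0
            continue
        qs[i] = min(1.0, (null_tail / null_side) / (obs_tail / obs_side))
    result["fdr_q"] = qs
    return result


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` genes in each set.

    p = P(X >= k) with population M = |universe|, K = |set ∩ universe| marked,
    n = |query| drawn; Benjamini-Hochberg across sets.
    """
    universe_set = set(universe)
    query_set = set(query)
    if not universe_set:
        raise ValueError("empty universe")
    if not query_set:
        raise ValueError("empty query")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    m_total = len(universe_set)
    n_query = len(query_set)
    rows = []
    for gene_set in collection:
        members = set(gene_set.genes) & universe_set
        k = len(members & query_set)
        big_k = len(members)
        p = float(hypergeom.sf(k - 1, m_total, big_k, n_query))
        rows.append(
            {
                "name": gene_set.name,
                "set_size": big_k,
                "overlap": k,
                "expected": n_query * big_k / m_total,
                "p_hyper": p,
            }
        )
    result = pd.DataFrame(rows, columns=["name", "set_size", "overlap", "expected", "p_hyper"])
    if len(result):
        result["bh_q"] = multipletests(result["p_hyper"].to_numpy(), method="fdr_bh")[1]
    else:
        result["bh_q"] = []
    return result


# ---------------------------------------------------------------------------
# Enrichment-map style similarity graph
# ---------------------------------------------------------------------------

def set_similarity(a, b) -> tuple[float, float]:
    """(jaccard, overlap_coefficient) of two gene sets."""
    a, b = set(a), set(b)
    inter = len(a & b)
    if inter == 0:
        return 0.0, 0.0
    return inter / len(a | b), inter / min(len(a), len(b))


def enrichment_graph(
    results: pd.DataFrame,
    collection: GeneSetCollection,
    p_cutoff: float = 0.05,
    similarity_cutoff: float = 0.5,
) -> nx.Graph:
    """Graph of sets significant at nominal p <= ``p_cutoff``, with edges
    between pairs whose overlap coefficient reaches ``similarity_cutoff``."""
    graph = nx.Graph()
    significant = results[results["p_nominal"] <= p_cutoff]
    for row in significant.itertuples(index=False):
        graph.add_node(
            row.name,
            es=row.es,
            nes=row.nes,
            p_nominal=row.p_nominal,
            fdr_q=row.fdr_q,
            size=row.size,
        )
    nodes = list(graph.nodes)
    for i, name_a in enumerate(nodes):
        genes_a = collection.get(name_a).genes
        for name_b in nodes[i + 1:]:
            jac, ovl = set_similarity(genes_a, collection.get(name_b).genes)
            if ovl >= similarity_cutoff and ovl > 0:
                graph.add_edge(name_a, name_b, jaccard=jac, overlap_coefficient=ovl)
    return graph


def write_graph(graph: nx.Graph, graphml_path, nodes_tsv=None, edges_tsv=None) -> None:
    nx.write_graphml(graph, graphml_path)
    if nodes_tsv is not None:
        pd.DataFrame(
            [{"name": n, **attrs} for n, attrs in graph.nodes(data=True)]
        ).to_csv(nodes_tsv, sep="\t", index=False)
    if edges_tsv is not None:
        pd.DataFrame(
            [{"set_a": a, "set_b": b, **attrs} for a, b, attrs in graph.edges(data=True)]
        ).to_csv(edges_tsv, sep="\t", index=False)
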