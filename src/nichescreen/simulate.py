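"""Synthetic blastocyst-like expression data with planted ground truth.

The generator emulates the statistical structure the downstream screen
assumes: three lineages (EPI, PE, TE by default) of single cells on an
RPKM-like scale, with

* per-gene log-normal baselines (log2 RPKM), lineage effects additive in
  log space and cell-to-cell biological noise,
* planted ligand-receptor circuits whose on-lineage medians sit above the
  expression threshold and whose off-lineage medians sit below it (the
  PE -> EPI IGF1/IGF1R motif is the template),
* decoy ligand-receptor pairs expressed below threshold everywhere, so the
  threshold rule rather than the pairing step must exclude them,
* planted overdispersed genes (extra biological log-variance) for the HVG
  stage, and planted lineage-enriched gene sets for the GSEA stage,
* independent Bernoulli dropout and optional multiplicative per-batch
  effects.

Counts are emitted as integers together with a gene-length table so the
RPKM stage is exercised. RPKM is compositional — the sum of RPKM * length
over genes is 1e9 by construction — so background expression is rescaled by
a single global factor to satisfy that identity on average; planted and
decoy genes keep their configured absolute RPKM levels. Count noise is
Poisson, realised by inverting the Poisson CDF on a pre-drawn uniform field;
this quantile coupling makes increasing the dropout rate (same seed) provably
never increase any gene's mean expression.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .enrichment import GeneSet, GeneSetCollection
from .expression import ExpressionMatrix
from .screen import LRCatalogue, PPITable


class ConfigurationError(ValueError):
    """The simulation configuration violates an invariant."""


@dataclass(frozen=True)
class PlantedCircuit:
    """A ligand-receptor circuit to plant: the ligand's median RPKM is set in
    the source lineage and the receptor's in the target lineage; both genes
    drop to ``off_lineage_rpkm`` everywhere else."""

    ligand_gene: str
    receptor_gene: str
    source_lineage: str
    target_lineage: str
    ligand_median_rpkm: float = 20.0
    receptor_median_rpkm: float = 12.0
    off_lineage_rpkm: float = 0.5


def default_planted_pairs() -> list[PlantedCircuit]:
    """The template PE -> EPI IGF-axis motif plus five further circuits
    covering the remaining lineage directions (one autocrine)."""
    return [
        PlantedCircuit("IGF1", "IGF1R", "PE", "EPI", 20.0, 12.0, 0.5),
        PlantedCircuit("LIGB", "RECB", "EPI", "TE", 15.0, 10.0, 0.4),
        PlantedCircuit("LIGC", "RECC", "TE", "PE", 25.0, 8.0, 0.5),
        PlantedCircuit("LIGD", "RECD", "EPI", "EPI", 12.0, 18.0, 0.6),
        PlantedCircuit("LIGE", "RECE", "PE", "TE", 30.0, 9.0, 0.3),
        PlantedCircuit("LIGF", "RECF", "TE", "EPI", 10.0, 14.0, 0.5),
    ]


def default_gene_sets() -> list[tuple[str, str, float]]:
    return [("SET_EPI_UP", "EPI", 2.0), ("SET_TE_UP", "TE", 2.0)]


@dataclass
class SimConfig:
    """Study conditions for the synthetic blastocyst dataset.

    Log-scale parameters are in log2 RPKM units. ``baseline_log_mean`` and
    ``gene_log_mean_sd`` set the across-gene spread of baselines;
    ``baseline_log_sd`` is the within-gene cell-to-cell biological noise.
    """

    n_genes: int = 2000
    cells_per_lineage: dict[str, int] = field(
        default_factory=lambda: {"EPI": 50, "PE": 50, "TE": 50}
    )
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.7
    gene_log_mean_sd: float = 2.0
    planted_pairs: list[PlantedCircuit] = field(default_factory=default_planted_pairs)
    n_decoy_pairs: int = 20
    decoy_rpkm: float = 0.5
    n_planted_hvgs: int = 100
    hvg_dispersion_multiplier: float = 5.0
    planted_gene_sets: list[tuple[str, str, float]] = field(default_factory=default_gene_sets)
    geneset_size: int = 50
    dropout_rate: float = 0.0
    n_batches: int = 1
    batch_log_sd: float = 0.0
    library_size: int = 500_000
    length_range: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not self.cells_per_lineage:
            raise ConfigurationError("at least one lineage is required")
        for lin, n in self.cells_per_lineage.items():
            if n <= 0:
                raise ConfigurationError(f"cells_per_lineage[{lin!r}] must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if self.n_batches <= 0:
            raise ConfigurationError("n_batches must be positive")
        if self.batch_log_sd < 0:
            raise ConfigurationError("batch_log_sd must be non-negative")
        if self.n_decoy_pairs < 0 or self.n_planted_hvgs < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.hvg_dispersion_multiplier <= 1.0:
            raise ConfigurationError("hvg_dispersion_multiplier must exceed 1")
        if self.baseline_log_sd <= 0:
            raise ConfigurationError("baseline_log_sd must be positive")
        circuit_genes: list[str] = []
        for c in self.planted_pairs:
            circuit_genes += [c.ligand_gene, c.receptor_gene]
            for lin in (c.source_lineage, c.target_lineage):
                if lin not in self.cells_per_lineage:
                    raise ConfigurationError(f"circuit lineage {lin!r} not in cells_per_lineage")
            if not (c.ligand_median_rpkm > c.off_lineage_rpkm
                    and c.receptor_median_rpkm > c.off_lineage_rpkm):
                raise ConfigurationError(
                    f"circuit {c.ligand_gene}/{c.receptor_gene}: on-target medians must "
                    "exceed the off-lineage level"
                )
        if len(circuit_genes) != len(set(circuit_genes)):
            raise ConfigurationError("planted circuit genes must be distinct")
        for name, lin, _effect in self.planted_gene_sets:
            if lin not in self.cells_per_lineage:
                raise ConfigurationError(f"gene set {name!r} targets unknown lineage {lin!r}")
        n_reserved = (
            len(circuit_genes)
            + 2 * self.n_decoy_pairs
            + self.n_planted_hvgs
            + self.geneset_size * len(self.planted_gene_sets)
        )
        if n_reserved > self.n_genes:
            raise ConfigurationError(
                f"planted genes ({n_reserved}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class GroundTruth:
    """What was planted, for downstream evaluation."""

    true_interactions: list[tuple[str, str, str, str]]
    decoy_pairs: list[tuple[str, str]]
    true_hvgs: list[str]
    true_enriched_sets: list[tuple[str, str]]
    enriched_set_members: dict[str, list[str]]
    all_genes: list[str]

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["true_interactions"] = [list(t) for t in self.true_interactions]
        payload["decoy_pairs"] = [list(t) for t in self.decoy_pairs]
        payload["true_enriched_sets"] = [list(t) for t in self.true_enriched_sets]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            true_interactions=[tuple(t) for t in payload["true_interactions"]],
            decoy_pairs=[tuple(t) for t in payload["decoy_pairs"]],
            true_hvgs=payload["true_hvgs"],
            true_enriched_sets=[tuple(t) for t in payload["true_enriched_sets"]],
            enriched_set_members=payload["enriched_set_members"],
            all_genes=payload["all_genes"],
        )


#: Sum over genes of RPKM * length implied by the definition of RPKM.
_RPKM_LENGTH_SUM = 1e9


def simulate_dataset(config: SimConfig):
    """Generate (counts ExpressionMatrix, gene lengths Series, GroundTruth).

    Deterministic given the config (including seed); identical configs give
    bit-identical outputs.
    """
    config.validate()
    root = np.random.default_rng(config.seed)
    rs_structure, rs_noise, rs_dropout, rs_counts = root.spawn(4)

    # --- gene panel layout -------------------------------------------------
    circuit_genes = []
    for c in config.planted_pairs:
        circuit_genes += [c.ligand_gene, c.receptor_gene]
    decoy_pairs = [
        (f"DECL{i + 1:03d}", f"DECR{i + 1:03d}") for i in range(config.n_decoy_pairs)
    ]
    decoy_genes = [g for pair in decoy_pairs for g in pair]
    n_background = config.n_genes - len(circuit_genes) - len(decoy_genes)
    background = [f"G{i + 1:05d}" for i in range(n_background)]
    genes = circuit_genes + decoy_genes + background
    gene_index = {g: i for i, g in enumerate(genes)}

    bg_pool = list(background)
    hvg_idx = rs_structure.choice(len(bg_pool), size=config.n_planted_hvgs, replace=False)
    true_hvgs = sorted(bg_pool[i] for i in hvg_idx)
    remaining = [g for g in bg_pool if g not in set(true_hvgs)]
    set_members: dict[str, list[str]] = {}
    for name, _lin, _eff in config.planted_gene_sets:
        pick = rs_structure.choice(len(remaining), size=config.geneset_size, replace=False)
        members = sorted(remaining[i] for i in pick)
        set_members[name] = members
        taken = set(members)
        remaining = [g for g in remaining if g not in taken]

    lineage_names = list(config.cells_per_lineage)
    lineage_of: list[int] = []
    cell_ids: list[str] = []
    for li, lin in enumerate(lineage_names):
        n = config.cells_per_lineage[lin]
        cell_ids += [f"{lin}_{i:04d}" for i in range(n)]
        lineage_of += [li] * n
    lineage_of = np.asarray(lineage_of)
    n_cells = len(cell_ids)
    batch_of = np.arange(n_cells) % config.n_batches

    lengths = rs_structure.integers(
        config.length_range[0], config.length_range[1] + 1, size=config.n_genes
    )

    # --- log2-RPKM means: baseline + lineage structure ---------------------
    mu = rs_structure.normal(config.baseline_log_mean, config.gene_log_mean_sd, config.n_genes)
    mu_lin = np.tile(mu[:, None], (1, len(lineage_names)))
    planted_mask = np.zeros(config.n_genes, dtype=bool)
    for c in config.planted_pairs:
        li_src = lineage_names.index(c.source_lineage)
        li_tgt = lineage_names.index(c.target_lineage)
        gi = gene_index[c.ligand_gene]
        mu_lin[gi, :] = np.log2(c.off_lineage_rpkm)
        mu_lin[gi, li_src] = np.log2(c.ligand_median_rpkm)
        planted_mask[gi] = True
        gi = gene_index[c.receptor_gene]
        mu_lin[gi, :] = np.log2(c.off_lineage_rpkm)
        mu_lin[gi, li_tgt] = np.log2(c.receptor_median_rpkm)
        planted_mask[gi] = True
    for ga, gb in decoy_pairs:
        for g in (ga, gb):
            mu_lin[gene_index[g], :] = np.log2(config.decoy_rpkm)
            planted_mask[gene_index[g]] = True
    for name, lin, effect in config.planted_gene_sets:
        li = lineage_names.index(lin)
        for g in set_members[name]:
            mu_lin[gene_index[g], li] += effect

    # Rescale the background so mean per-cell sum(rpkm * length) hits 1e9;
    # planted/decoy genes keep their configured absolute levels.
    noise_sd = np.full(config.n_genes, config.baseline_log_sd)
    for g in true_hvgs:
        noise_sd[gene_index[g]] *= np.sqrt(config.hvg_dispersion_multiplier)
    lognormal_mean_factor = np.exp(0.5 * (noise_sd * np.log(2.0)) ** 2)
    # calibration targets the dropout-free field so that raising the dropout
    # rate can only remove counts, never rescale the background upward
    expected_rpkm = (2.0 ** mu_lin).mean(axis=1) * lognormal_mean_factor
    expected_sum = float((expected_rpkm * lengths).sum())
    planted_sum = float((expected_rpkm[planted_mask] * lengths[planted_mask]).sum())
    bg_sum = expected_sum - planted_sum
    if bg_sum > 0:
        bg_target = max(_RPKM_LENGTH_SUM - planted_sum, 1e-3 * _RPKM_LENGTH_SUM)
        mu_lin[~planted_mask, :] += np.log2(bg_target / bg_sum)

    # --- per-cell expression on the RPKM scale -----------------------------
    batch_fx = np.zeros((config.n_genes, config.n_batches))
    if config.n_batches > 1 and config.batch_log_sd > 0:
        batch_fx = rs_structure.normal(
            0.0, config.batch_log_sd, (config.n_genes, config.n_batches)
        )
    log_expr = (
        mu_lin[:, lineage_of]
        + batch_fx[:, batch_of]
        + rs_noise.normal(0.0, 1.0, (config.n_genes, n_cells)) * noise_sd[:, None]
    )
    e = 2.0 ** log_expr
    dropout_u = rs_dropout.random((config.n_genes, n_cells))
    e[dropout_u < config.dropout_rate] = 0.0

    # --- counts via Poisson quantile coupling ------------------------------
    lam = e * lengths[:, None] * (config.library_size / _RPKM_LENGTH_SUM)
    count_u = rs_counts.random((config.n_genes, n_cells))
    counts = poisson.ppf(count_u, lam)
    counts = np.maximum(np.asarray(np.nan_to_num(counts, nan=0.0), dtype=np.int64), 0)

    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cell_ids)
    annotations = pd.DataFrame(
        {
            "lineage": [lineage_names[i] for i in lineage_of],
            "batch": [f"batch{i}" for i in batch_of],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    matrix = ExpressionMatrix(values, annotations, "counts")
    length_series = pd.Series(lengths, index=pd.Index(genes, name="gene"), name="length_bp")
    truth = GroundTruth(
        true_interactions=[
            (c.ligand_gene, c.receptor_gene, c.source_lineage, c.target_lineage)
            for c in config.planted_pairs
        ],
        decoy_pairs=decoy_pairs,
        true_hvgs=true_hvgs,
        true_enriched_sets=[(name, lin) for name, lin, _ in config.planted_gene_sets],
        enriched_set_members=set_members,
        all_genes=genes,
    )
    return matrix, length_series, truth


# ---------------------------------------------------------------------------
# Toy companions for the planted truth
# ---------------------------------------------------------------------------

def build_toy_catalogue(truth: GroundTruth, config: SimConfig) -> tuple[LRCatalogue, PPITable]:
    """Catalogue and PPI table covering exactly the planted circuits and
    decoy pairs: circuit genes carry their true roles and an edge links each
    circuit; decoy pairs get both annotations and an edge, so only the
    expression threshold can exclude them."""
    entries = []
    edges = []
    for lig, rec, _src, _tgt in truth.true_interactions:
        entries.append({"gene": lig, "role": "ligand", "pathways": "TOY_SIGNALLING"})
        entries.append({"gene": rec, "role": "receptor", "pathways": "TOY_SIGNALLING"})
        edges.append({"gene_a": min(lig, rec), "gene_b": max(lig, rec), "confidence": 0.9})
    for ga, gb in truth.decoy_pairs:
        entries.append({"gene": ga, "role": "ligand", "pathways": "TOY_SIGNALLING"})
        entries.append({"gene": gb, "role": "receptor", "pathways": "TOY_SIGNALLING"})
        edges.append({"gene_a": min(ga, gb), "gene_b": max(ga, gb), "confidence": 0.8})
    cat = pd.DataFrame(entries, columns=["gene", "role", "pathways"]).drop_duplicates(
        subset=["gene", "role"]
    )
    ppi = pd.DataFrame(edges, columns=["gene_a", "gene_b", "confidence"]).drop_duplicates(
        subset=["gene_a", "gene_b"]
    )
    return LRCatalogue(cat.reset_index(drop=True)), PPITable(ppi.reset_index(drop=True))


def build_toy_genesets(
    truth: GroundTruth,
    n_background: int = 10,
    background_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Planted enriched sets first, then seeded random background sets drawn
    from the full gene universe."""
    rng = np.random.default_rng(seed)
    sets = [
        GeneSet(name, f"planted:{lineage}", list(truth.enriched_set_members[name]))
        for name, lineage in truth.true_enriched_sets
    ]
    universe = np.asarray(truth.all_genes, dtype=object)
    size = min(background_size, len(universe))
    for i in range(n_background):
        members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        sets.append(GeneSet(f"BG_{i + 1:03d}", "background", members))
    return GeneSetCollection(sets)
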