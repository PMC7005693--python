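"""Lineage-resolved ligand-receptor interaction screen.

The core procedure: curated ligands and receptors (as extracted from signal
transduction pathways) are paired through protein-protein interaction
evidence, and a directed lineage-to-lineage interaction is called whenever
the ligand's median RPKM in the source lineage and the receptor's median
RPKM in the target lineage both reach the expression threshold (5 RPKM by
default, boundary counted as expressed). The template motif is a
primitive-endoderm ligand signalling to an epiblast receptor (IGF1 -> IGF1R).

An explicit specificity score quantifies how lineage-restricted a call is:
fold(g, k) = (median_{g,k} + psi) / (max over other lineages + psi), and the
call's score is the weaker of its ligand and receptor folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from itertools import product

import numpy as np
import pandas as pd

from .expression import FormatError, LineageMedianTable, ScaleError

logger = logging.getLogger(__name__)

ROLES = ("ligand", "receptor")

#: Expression threshold in RPKM: a gene with per-lineage median at or above
#: this value counts as expressed in that lineage.
DEFAULT_THRESHOLD = 5.0


@dataclass
class LRCatalogue:
    """Ligand/receptor role annotations; a gene may carry both roles."""

    entries: pd.DataFrame  # columns: gene, role, pathways

    @property
    def ligands(self) -> set[str]:
        e = self.entries
        return set(e.loc[e["role"] == "ligand", "gene"])

    @property
    def receptors(self) -> set[str]:
        e = self.entries
        return set(e.loc[e["role"] == "receptor", "gene"])

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


@dataclass
class PPITable:
    """Undirected scored protein-protein interaction edges.

    Edges are stored in canonical (sorted) gene order with duplicates
    collapsed to the maximum reported confidence.
    """

    edges: pd.DataFrame  # columns: gene_a, gene_b, confidence

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self, min_confidence: float = 0.0) -> dict[tuple[str, str], float]:
        keep = self.edges[self.edges["confidence"] >= min_confidence]
        return {
            tuple(sorted((a, b))): c
            for a, b, c in keep.itertuples(index=False)
        }

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


@dataclass
class InteractionCall:
    """A directed lineage-to-lineage ligand-receptor candidate."""

    ligand: str
    receptor: str
    source_lineage: str
    target_lineage: str
    ligand_median: float
    receptor_median: float
    ligand_expressed: bool
    receptor_expressed: bool
    interaction_class: str  # "autocrine" | "paracrine"
    threshold: float
    specificity_score: float = math.nan


def _normalise_symbol(sym: str) -> str:
    sym = str(sym).strip().upper()
    if sym.endswith("_HUMAN"):  # HIPPIE UniProt-style symbols
        sym = sym[: -len("_HUMAN")]
    return sym


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_catalogue(path) -> LRCatalogue:
    """Read a ligand/receptor catalogue TSV (gene, role, pathways).

    Role tokens other than ligand/receptor raise with the offending line
    number; duplicated (gene, role) rows are collapsed, pathway annotations
    merged.
    """
    rows: dict[tuple[str, str], set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "gene":
                continue  # header
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least gene and role columns")
            gene = _normalise_symbol(parts[0])
            role = parts[1].strip().lower()
            if role not in ROLES:
                raise FormatError(
                    f"{path}:{lineno}: unknown role token {parts[1]!r} (expected ligand/receptor)"
                )
            pathways = set()
            if len(parts) > 2 and parts[2].strip():
                pathways = {p.strip() for p in parts[2].split(";") if p.strip()}
            rows.setdefault((gene, role), set()).update(pathways)
    entries = pd.DataFrame(
        [
            {"gene": g, "role": r, "pathways": ";".join(sorted(p))}
            for (g, r), p in sorted(rows.items())
        ],
        columns=["gene", "role", "pathways"],
    )
    return LRCatalogue(entries)


def load_ppi(path) -> PPITable:
    """Read a PPI table in either the 3-column dialect (gene_a, gene_b,
    confidence) or the HIPPIE dialect (symbol, id, symbol, id, confidence,
    metadata). Confidence defaults to 1.0 when absent; duplicate edges (in
    either orientation) collapse to the maximum confidence."""
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() in ("gene_a", "gene1", "symbol_a"):
                continue  # header
            if len(parts) >= 5:
                # HIPPIE dialect: symbol, entrez id, symbol, entrez id, score, [metadata]
                a, b, conf_str = parts[0], parts[2], parts[4]
            elif len(parts) >= 2:
                a, b = parts[0], parts[1]
                conf_str = parts[2] if len(parts) > 2 and parts[2].strip() else "1.0"
            else:
                raise FormatError(f"{path}:{lineno}: expected at least two gene columns")
            try:
                conf = float(conf_str)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad confidence {conf_str!r}") from exc
            if not 0.0 <= conf <= 1.0:
                raise FormatError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
            key = tuple(sorted((_normalise_symbol(a), _normalise_symbol(b))))
            edges[key] = max(conf, edges.get(key, 0.0))
    frame = pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "confidence": c} for (a, b), c in sorted(edges.items())],
        columns=["gene_a", "gene_b", "confidence"],
    )
    return PPITable(frame)


# ---------------------------------------------------------------------------
# Pairing and calling
# ---------------------------------------------------------------------------

def pair_by_ppi(
    catalogue: LRCatalogue, ppi: PPITable, min_confidence: float = 0.0
) -> pd.DataFrame:
    """All (ligand, receptor) pairs backed by a PPI edge at or above
    ``min_confidence``. A dual-role gene may appear on either side but is
    never paired with itself. Returns a DataFrame (ligand, receptor,
    confidence) sorted lexicographically."""
    ligands = catalogue.ligands
    receptors = catalogue.receptors
    pairs: dict[tuple[str, str], float] = {}
    for (a, b), conf in ppi.edge_set(min_confidence).items():
        if a != b:
            if a in ligands and b in receptors:
                pairs[(a, b)] = max(conf, pairs.get((a, b), 0.0))
            if b in ligands and a in receptors:
                pairs[(b, a)] = max(conf, pairs.get((b, a), 0.0))
    return pd.DataFrame(
        [{"ligand": l, "receptor": r, "confidence": c} for (l, r), c in sorted(pairs.items())],
        columns=["ligand", "receptor", "confidence"],
    )


def call_interactions(
    pairs: pd.DataFrame,
    medians: LineageMedianTable,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = True,
) -> list[InteractionCall]:
    """Emit a call for every pair and ordered lineage combination where the
    ligand and receptor medians both reach the RPKM threshold.

    The boundary is assigned to "expressed" by default (``inclusive``);
    genes absent from the median table are skipped with a warning.
    """
    if medians.scale != "rpkm":
        raise ScaleError(f"median table is on scale {medians.scale!r}; RPKM required")
    table = medians.values
    lineage_names = list(table.columns)
    passes = (lambda v: v >= threshold) if inclusive else (lambda v: v > threshold)
    calls: list[InteractionCall] = []
    for row in pairs.itertuples(index=False):
        lig, rec = row.ligand, row.receptor
        absent = [g for g in (lig, rec) if g not in table.index]
        if absent:
            logger.warning("pair (%s, %s): gene(s) %s absent from medians; skipped", lig, rec, absent)
            continue
        for src, tgt in product(lineage_names, lineage_names):
            lm = float(table.at[lig, src])
            rm = float(table.at[rec, tgt])
            if passes(lm) and passes(rm):
                calls.append(
                    InteractionCall(
                        ligand=lig,
                        receptor=rec,
                        source_lineage=src,
                        target_lineage=tgt,
                        ligand_median=lm,
                        receptor_median=rm,
                        ligand_expressed=True,
                        receptor_expressed=True,
                        interaction_class="autocrine" if src == tgt else "paracrine",
                        threshold=threshold,
                    )
                )
    return calls


def _specificity_fold(
    table: pd.DataFrame, gene: str, lineage: str, pseudocount: float
) -> float:
    m_on = float(table.at[gene, lineage])
    off = table.loc[gene, table.columns != lineage]
    return (m_on + pseudocount) / (float(off.max()) + pseudocount)


def rank_interactions(
    calls: list[InteractionCall],
    medians: LineageMedianTable,
    pseudocount: float = 1.0,
) -> list[InteractionCall]:
    """Attach specificity scores and sort calls by decreasing score.

    score = min(fold(ligand, source), fold(receptor, target)), where fold is
    the pseudocounted ratio of the on-lineage median to the best off-lineage
    median. Ties break lexicographically by (ligand, receptor).
    """
    table = medians.values
    if table.shape[1] < 2:
        raise ValueError("specificity needs at least two lineages as off-lineage reference")
    scored = []
    for call in calls:
        lig_fold = _specificity_fold(table, call.ligand, call.source_lineage, pseudocount)
        rec_fold = _specificity_fold(table, call.receptor, call.target_lineage, pseudocount)
        call.specificity_score = min(lig_fold, rec_fold)
        scored.append(call)
    scored.sort(key=lambda c: (-c.specificity_score, c.ligand, c.receptor))
    return scored


def calls_to_frame(calls: list[InteractionCall]) -> pd.DataFrame:
    cols = [f.name for f in fields(InteractionCall)]
    return pd.DataFrame([{c: getattr(call, c) for c in cols} for call in calls], columns=cols)


def write_calls(calls: list[InteractionCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)
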