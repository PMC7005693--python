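"""Expression containers, I/O, normalisation and summary statistics.

The screen operates on gene x cell matrices whose values can live on one of
four scales — raw ``counts``, ``rpkm`` (reads per kilobase of transcript per
million mapped reads), size-factor ``normalised`` counts, or ``log2``
(log2(x + 1)) — tracked by an explicit scale tag.  Every numerical operation
declares which scale it accepts and refuses mismatched input, so a pipeline
cannot silently, say, RPKM-transform already-normalised data.

Cell annotations carry the blastocyst lineage (EPI, PE, TE by convention,
though any labels work) and a batch label; the per-lineage median is the
summary statistic the downstream ligand-receptor screen consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

#: Recognised scale tags, in the order a typical pipeline produces them.
SCALES = ("counts", "rpkm", "normalised", "log2")


class FormatError(ValueError):
    """An input file or matrix violates the format contract."""


class ScaleError(ValueError):
    """An operation received a matrix on the wrong scale."""


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values plus per-cell lineage/batch annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per cell. All values
        must be non-negative and both indices unique.
    annotations
        DataFrame indexed by cell id with at least a ``lineage`` column; a
        ``batch`` column is added (single batch) when absent. Rows must match
        the matrix columns exactly.
    scale
        One of :data:`SCALES`.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()][:5].tolist()
            raise FormatError(f"duplicate gene identifiers: {dup}")
        if not v.columns.is_unique:
            dup = v.columns[v.columns.duplicated()][:5].tolist()
            raise FormatError(f"duplicate cell identifiers: {dup}")
        arr = v.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise FormatError("negative expression values are not allowed")
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        ann = self.annotations
        if "lineage" not in ann.columns:
            raise FormatError("annotations must have a 'lineage' column")
        if "batch" not in ann.columns:
            ann = ann.assign(batch="batch0")
        missing = v.columns.difference(ann.index)
        if len(missing):
            raise FormatError(
                "cell(s) missing from annotations: " + ", ".join(map(str, missing[:10]))
            )
        extra = ann.index.difference(v.columns)
        if len(extra):
            raise FormatError(
                "annotation row(s) without a matrix column: " + ", ".join(map(str, extra[:10]))
            )
        # align annotation order to the matrix column order
        self.annotations = ann.loc[v.columns]

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def lineages(self) -> list[str]:
        """Lineage labels in order of first appearance."""
        return list(dict.fromkeys(self.annotations["lineage"]))

    def cells_of(self, lineage: str) -> pd.Index:
        mask = self.annotations["lineage"] == lineage
        if not mask.any():
            raise ValueError(f"lineage {lineage!r} has no cells")
        return self.annotations.index[mask]

    def require_scale(self, *allowed: str) -> None:
        if self.scale not in allowed:
            raise ScaleError(
                f"matrix is on scale {self.scale!r}; this operation requires {allowed}"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path, annotation_path) -> None:
    """Write a gene x cell TSV (first column = gene) and an annotation TSV."""
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    matrix.annotations.to_csv(annotation_path, sep="\t", index_label="cell_id")


def read_matrix(path, annotation_path, scale: str = "counts") -> ExpressionMatrix:
    """Read a matrix from TSV (or an MTX triplet directory) plus annotations."""
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        values = _read_mtx_triplet(path if path.is_dir() else path.parent)
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    ann.index = ann.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, ann, scale)


def write_mtx(matrix: ExpressionMatrix, out_dir) -> None:
    """Write the MatrixMarket triplet (matrix.mtx, genes.tsv, barcodes.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coo = sparse.coo_matrix(matrix.values.to_numpy())
    spio.mmwrite(out_dir / "matrix.mtx", coo, precision=17)
    pd.Series(matrix.gene_ids).to_csv(out_dir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.cell_ids).to_csv(
        out_dir / "barcodes.tsv", sep="\t", index=False, header=False
    )


def _read_mtx_triplet(mtx_dir: Path) -> pd.DataFrame:
    mat = spio.mmread(mtx_dir / "matrix.mtx").toarray()
    genes = pd.read_csv(mtx_dir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(mtx_dir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    return pd.DataFrame(mat, index=genes, columns=cells)


def read_gene_lengths(path) -> pd.Series:
    """Read a gene length TSV (columns: gene, length_bp)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("gene length table needs two columns (gene, length_bp)")
    lengths = pd.Series(
        df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="length_bp"
    )
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][:5].tolist()
        raise FormatError(f"non-positive gene length for: {bad}")
    return lengths


def write_gene_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------

def rpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM_gj = c_gj * 1e9 / (L_g * T_j) with T_j the total counts of cell j.
    Scale-invariant within a cell: doubling every count of a cell leaves its
    RPKM unchanged.
    """
    counts.require_scale("counts")
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise FormatError(
            "missing gene length for: " + ", ".join(map(str, missing[:10]))
        )
    L = lengths.reindex(counts.gene_ids).to_numpy(float)
    if (L <= 0).any():
        raise FormatError("gene lengths must be positive")
    totals = counts.values.sum(axis=0)
    zero = totals.index[totals.to_numpy() == 0]
    if len(zero):
        raise FormatError("cell(s) with zero total counts: " + ", ".join(map(str, zero[:10])))
    vals = counts.values.to_numpy(float) * 1e9 / (L[:, None] * totals.to_numpy(float)[None, :])
    out = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.cell_ids)
    return ExpressionMatrix(out, counts.annotations.copy(), "rpkm")


def _median_of_ratios(X: np.ndarray) -> np.ndarray:
    """Per-column median of ratios to the gene-wise geometric-mean reference.

    Genes must be positive in every column to enter the reference (the DESeq
    convention); if no such gene exists, fall back to a pseudo-reference of
    per-gene geometric means over nonzero entries, with a logged warning.
    """
    all_pos = (X > 0).all(axis=1)
    if all_pos.any():
        sub = X[all_pos]
        ref = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    else:
        logger.warning(
            "no gene expressed in every cell; using pseudo-reference of "
            "geometric means over nonzero entries"
        )
        with np.errstate(divide="ignore"):
            lg = np.where(X > 0, np.log(np.where(X > 0, X, 1.0)), np.nan)
        ref = np.exp(np.nanmean(lg, axis=1))
        usable = np.isfinite(ref) & (ref > 0)
        if not usable.any():
            raise FormatError("matrix has no nonzero entries; cannot compute size factors")
        ratios = np.where(X[usable] > 0, X[usable] / ref[usable, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(factors)) or np.any(factors <= 0):
        raise FormatError("size factor computation produced non-positive factors")
    return factors


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors (raw, DESeq-style).

    All cells identical gives factors of exactly 1; scaling one cell's counts
    by c scales its factor by c relative to the others.
    """
    counts.require_scale("counts")
    sf = _median_of_ratios(counts.values.to_numpy(float))
    return pd.Series(sf, index=counts.cell_ids, name="size_factor")


def normalise_by_size_factors(
    counts: ExpressionMatrix, depth_scale: float = 1e6
) -> ExpressionMatrix:
    """Size-factor-normalised counts, invariant to per-cell count rescaling.

    Each cell is first brought to a common depth (``depth_scale`` total
    counts), then the median-of-ratios factor of the depth-scaled matrix is
    divided out. Because the depth scaling removes per-cell totals before the
    geometric-mean reference is formed, multiplying any cell's raw counts by
    c > 0 leaves the normalised matrix bit-for-bit unchanged (up to floating
    point), which the raw ``counts / size_factor`` quotient does not achieve.
    """
    counts.require_scale("counts")
    X = counts.values.to_numpy(float)
    totals = X.sum(axis=0)
    zero = counts.cell_ids[totals == 0]
    if len(zero):
        raise FormatError("cell(s) with zero total counts: " + ", ".join(map(str, zero[:10])))
    depth_scaled = X * (depth_scale / totals)[None, :]
    dev = _median_of_ratios(depth_scaled)
    vals = depth_scaled / dev[None, :]
    out = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.cell_ids)
    return ExpressionMatrix(out, counts.annotations.copy(), "normalised")


def log2p1(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); accepts any non-log scale."""
    matrix.require_scale("counts", "rpkm", "normalised")
    arr = matrix.values.to_numpy(float)
    if arr.size and np.nanmin(arr) < 0:
        raise FormatError("negative values cannot be log-transformed")
    out = pd.DataFrame(np.log2(arr + 1.0), index=matrix.gene_ids, columns=matrix.cell_ids)
    return ExpressionMatrix(out, matrix.annotations.copy(), "log2")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class LineageMedianTable:
    """Gene x lineage medians, tagged with the scale they were computed on."""

    values: pd.DataFrame
    scale: str

    @property
    def lineage_names(self) -> list[str]:
        return list(self.values.columns)

    def get(self, gene: str, lineage: str) -> float:
        return float(self.values.at[gene, lineage])

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


def lineage_medians(
    matrix: ExpressionMatrix, lineages: list[str] | None = None
) -> LineageMedianTable:
    """Per-gene, per-lineage sample medians (even n: mean of the central pair)."""
    labels = matrix.annotations["lineage"]
    if lineages is not None:
        empty = [lin for lin in lineages if (labels == lin).sum() == 0]
        if empty:
            raise ValueError(f"lineage(s) with zero cells: {empty}")
    med = matrix.values.T.groupby(labels, sort=False).median().T
    if lineages is not None:
        med = med[lineages]
    return LineageMedianTable(med, matrix.scale)


@dataclass
class BoxStats:
    """Tukey boxplot summary: quartiles, 1.5 IQR whiskers, outliers."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list = field(default_factory=list)
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
            "n": self.n,
        }


def boxplot_stats(values) -> BoxStats:
    """Quartiles by linear interpolation, whiskers at the most extreme data
    within 1.5 IQR of the box, everything beyond reported as outliers."""
    a = np.asarray(values, dtype=float)
    if a.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, med, q3 = np.percentile(a, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = a[(a >= lo_fence) & (a <= hi_fence)]
    outliers = a[(a < lo_fence) | (a > hi_fence)]
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(x) for x in outliers),
        n=int(a.size),
    )
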