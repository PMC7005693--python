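"""Small quantitative culture and embryo assays.

Population doublings between successive viable-cell counts use the printed
constant 0.30103 (log10 of 2 to five decimals) verbatim:

    PDL = log10(N_t / N_{t-1}) / 0.30103

Embryo lineage proportions express NANOG+ (epiblast), SOX17+ (primitive
endoderm) and their sum (inner cell mass) as percentages of total nuclei,
and groups are compared with a one-tailed two-sample Student t-test
(pooled variance by default; Welch behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

#: Denominator of the population-doubling formula, used verbatim.
DOUBLING_CONSTANT = 0.30103


@dataclass(frozen=True)
class GrowthRecord:
    timepoint: float
    viable_count: float


def population_doublings(records) -> pd.DataFrame:
    """Per-interval and cumulative population doublings.

    ``records`` is a sequence of (timepoint, viable_count) pairs or
    GrowthRecord objects with strictly increasing timepoints and positive
    counts; at least two records are required.
    """
    parsed = [
        r if isinstance(r, GrowthRecord) else GrowthRecord(float(r[0]), float(r[1]))
        for r in records
    ]
    if len(parsed) < 2:
        raise ValueError("population doublings need at least two records")
    for rec in parsed:
        if rec.viable_count <= 0:
            raise ValueError(f"non-positive viable count at timepoint {rec.timepoint}")
    times = [r.timepoint for r in parsed]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("timepoints must be strictly increasing")
    rows = []
    cumulative = 0.0
    for prev, cur in zip(parsed, parsed[1:]):
        pdl = math.log10(cur.viable_count / prev.viable_count) / DOUBLING_CONSTANT
        cumulative += pdl
        rows.append(
            {
                "t_start": prev.timepoint,
                "t_end": cur.timepoint,
                "pdl": pdl,
                "cumulative_pdl": cumulative,
            }
        )
    return pd.DataFrame(rows, columns=["t_start", "t_end", "pdl", "cumulative_pdl"])


def read_growth_tsv(path) -> list[GrowthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [GrowthRecord(float(t), float(n)) for t, n in zip(df.iloc[:, 0], df.iloc[:, 1])]


@dataclass(frozen=True)
class EmbryoCount:
    embryo_id: str
    group: str  # "control" | "treated"
    total_nuclei: int
    nanog_pos: int
    sox17_pos: int


def lineage_proportions(counts) -> pd.DataFrame:
    """Per-embryo marker percentages: %NANOG, %SOX17 and %ICM (their sum).

    %X = 100 * X / total_nuclei; the inner cell mass is identified solely by
    the combined NANOG+ and SOX17+ totals, so %ICM = %NANOG + %SOX17 exactly.
    """
    rows = []
    for c in counts:
        if not isinstance(c, EmbryoCount):
            c = EmbryoCount(str(c[0]), str(c[1]), int(c[2]), int(c[3]), int(c[4]))
        if c.total_nuclei <= 0:
            raise ValueError(f"embryo {c.embryo_id}: total nuclei must be positive")
        if c.nanog_pos < 0 or c.sox17_pos < 0:
            raise ValueError(f"embryo {c.embryo_id}: negative marker count")
        if c.nanog_pos + c.sox17_pos > c.total_nuclei:
            raise ValueError(
                f"embryo {c.embryo_id}: marker totals exceed total nuclei"
            )
        pct_nanog = 100.0 * c.nanog_pos / c.total_nuclei
        pct_sox17 = 100.0 * c.sox17_pos / c.total_nuclei
        rows.append(
            {
                "embryo_id": c.embryo_id,
                "group": c.group,
                "total_nuclei": c.total_nuclei,
                "pct_nanog": pct_nanog,
                "pct_sox17": pct_sox17,
                "pct_icm": pct_nanog + pct_sox17,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["embryo_id", "group", "total_nuclei", "pct_nanog", "pct_sox17", "pct_icm"],
    )


def read_embryo_tsv(path) -> list[EmbryoCount]:
    df = pd.read_csv(path, sep="\t")
    return [
        EmbryoCount(str(r[0]), str(r[1]), int(r[2]), int(r[3]), int(r[4]))
        for r in df.itertuples(index=False)
    ]


def one_tailed_t(group_a, group_b, direction: str = "b_gt_a", welch: bool = False):
    """One-tailed two-sample t-test.

    ``direction`` is ``"b_gt_a"`` (alternative: mean of b exceeds mean of a)
    or ``"a_gt_b"``. The returned t statistic is signed for the tested
    direction, so positive t supports the alternative. Pooled-variance
    Student test by default; ``welch=True`` drops the equal-variance
    assumption (Welch-Satterthwaite degrees of freedom).

    Returns (t, df, p).
    """
    if direction not in ("a_gt_b", "b_gt_a"):
        raise ValueError("direction must be 'a_gt_b' or 'b_gt_a'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            raise ValueError("zero variance in both groups; t undefined")
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if pooled == 0:
            raise ValueError("zero pooled variance; t undefined")
        se2 = pooled * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    diff = (b.mean() - a.mean()) if direction == "b_gt_a" else (a.mean() - b.mean())
    t_stat = diff / math.sqrt(se2)
    p = float(t_dist.sf(t_stat, df))
    return float(t_stat), float(df), p
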