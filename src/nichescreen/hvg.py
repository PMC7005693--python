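"""Highly variable gene selection from the mean-variance trend.

A smooth trend fitted to per-gene variance against per-gene mean of the
log-transformed normalised matrix is taken to represent the technical
component of the variance; genes whose total variance significantly exceeds
the trend carry biological variability. Significance comes from an upper-tail
chi-square ratio test, (n - 1) * total_var / tech_var against chi2(n - 1),
followed by Benjamini-Hochberg correction at alpha = 0.01 by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: Floor applied to the fitted technical variance (the trend can dip to or
#: below zero at the extremes of the mean range).
TECH_VAR_FLOOR = 1e-8


def select_hvgs(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    span: float = 0.3,
    tech_var_floor: float = TECH_VAR_FLOOR,
) -> pd.DataFrame:
    """Decompose per-gene variance into trend (technical) and excess
    (biological) components and flag significant genes.

    Parameters
    ----------
    matrix
        Log-scale matrix (``log2`` tag), at least 10 genes and 3 cells.
    alpha
        Benjamini-Hochberg significance level.
    span
        Lowess span for the mean-variance trend.

    Returns
    -------
    DataFrame indexed by gene with columns ``mean``, ``total_var``,
    ``tech_var``, ``bio_var``, ``p_value``, ``bh_q``, ``is_hvg``.
    """
    matrix.require_scale("log2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n_genes, n_cells = matrix.values.shape
    if n_genes < 10:
        raise ValueError(f"need at least 10 genes, got {n_genes}")
    if n_cells < 3:
        raise ValueError(f"need at least 3 cells, got {n_cells}")

    X = matrix.values.to_numpy(float)
    mean = X.mean(axis=1)
    total_var = X.var(axis=1, ddof=1)
    if np.ptp(mean) == 0:
        raise ValueError("degenerate gene means: cannot fit a mean-variance trend")

    tech_var = lowess(total_var, mean, frac=span, return_sorted=False)
    n_floored = int((tech_var < tech_var_floor).sum())
    if n_floored:
        logger.warning(
            "mean-variance trend floored at %.1e for %d gene(s)", tech_var_floor, n_floored
        )
    tech_var = np.maximum(tech_var, tech_var_floor)

    df = n_cells - 1
    stat = df * total_var / tech_var
    p = chi2.sf(stat, df)
    q = multipletests(p, method="fdr_bh")[1]
    bio_var = total_var - tech_var
    is_hvg = (q <= alpha) & (bio_var > 0)

    return pd.DataFrame(
        {
            "mean": mean,
            "total_var": total_var,
            "tech_var": tech_var,
            "bio_var": bio_var,
            "p_value": p,
            "bh_q": q,
            "is_hvg": is_hvg,
        },
        index=matrix.gene_ids,
    )
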