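"""Fold-change ranking of genes in a gated subset versus a reference.

Counts are library-size normalized to counts-per-10k per cell, averaged
over the gated cells of each side, and compared on a log2 scale with a
pseudocount:

    log2FC(g) = log2((mean_sample(g) + c) / (mean_ref(g) + c))

The full ranking (descending log2FC) is returned; report helpers extract
the top/bottom blocks.  No significance testing is attached: the output is
a ranking statistic, mirroring top-10 up/down gene reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 1e4


@dataclass
class DERanking:
    """Genes ordered by descending log2 fold change."""

    gene_ids: list[str]
    log_fc: np.ndarray
    mean_sample: np.ndarray
    mean_ref: np.ndarray

    def __post_init__(self) -> None:
        self.log_fc = np.asarray(self.log_fc, dtype=float)
        if not np.isfinite(self.log_fc).all():
            raise ValueError("log fold changes must be finite")
        if np.any(np.diff(self.log_fc) > 0):
            raise ValueError("ranking must be ordered by descending log2 FC")

    def top(self, n: int) -> pd.DataFrame:
        return self.to_frame().head(n)

    def bottom(self, n: int) -> pd.DataFrame:
        return self.to_frame().tail(n).iloc[::-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "log2_fc": self.log_fc,
                "mean_sample": self.mean_sample,
                "mean_ref": self.mean_ref,
            }
        )


def normalize_cpm(expr: ExpressionMatrix, scale: float = DEFAULT_SCALE) -> ExpressionMatrix:
    """Scale each cell's counts to sum to ``scale`` (counts-per-10k).

    Cells with zero total count are dropped (logged); an all-zero matrix is
    an error.
    """
    totals = expr.counts.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("every cell has zero total count")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d zero-count cells before normalization", dropped)
    counts = expr.counts[keep].astype(float)
    normalized = counts * (scale / totals[keep][:, None])
    cell_ids = [c for c, k in zip(expr.cell_ids, keep) if k]
    return ExpressionMatrix(cell_ids, list(expr.gene_ids), normalized)


def rank_fold_changes(
    expr_sample: ExpressionMatrix,
    expr_ref: ExpressionMatrix,
    cells_sample: set[str],
    cells_ref: set[str],
    pseudocount: float = 1.0,
    scale: float = DEFAULT_SCALE,
) -> DERanking:
    """Rank genes by log2 fold change of the gated sample vs reference subset."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    genes = [g for g in expr_sample.gene_ids if g in set(expr_ref.gene_ids)]
    if not genes:
        raise ValueError("sample and reference share no genes")
    n_union = len(set(expr_sample.gene_ids) | set(expr_ref.gene_ids))
    if len(genes) < n_union:
        logger.info("using %d shared genes of %d total", len(genes), n_union)

    mean_s = _subset_means(expr_sample, cells_sample, genes, scale)
    mean_r = _subset_means(expr_ref, cells_ref, genes, scale)
    # difference of logs (not log of ratio) so swapping sides negates exactly
    log_fc = np.log2(mean_s + pseudocount) - np.log2(mean_r + pseudocount)

    order = sorted(range(len(genes)), key=lambda i: (-log_fc[i], genes[i]))
    return DERanking(
        gene_ids=[genes[i] for i in order],
        log_fc=log_fc[order],
        mean_sample=mean_s[order],
        mean_ref=mean_r[order],
    )


def _subset_means(expr: ExpressionMatrix, cells: set[str], genes: list[str],
                  scale: float) -> np.ndarray:
    mask = np.array([c in cells for c in expr.cell_ids])
    if not mask.any():
        raise ValueError("gated subset is empty")
    normalized = normalize_cpm(
        ExpressionMatrix(
            [c for c, m in zip(expr.cell_ids, mask) if m],
            list(expr.gene_ids),
            expr.counts[mask],
        ),
        scale=scale,
    )
    cols = [normalized.gene_index(g) for g in genes]
    return normalized.counts[:, cols].mean(axis=0)
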