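"""Count normalization: FPKM, low-expression filtering, mean normalization.

The chain mirrors standard bulk RNA-seq practice for this kind of
analysis: counts are converted to FPKM using transcript lengths and
per-sample mapped-read totals, transcripts whose FPKM never reaches 1 in
any sample are discarded, and each surviving gene is divided by its mean
across samples so that factorization sees relative variation rather than
absolute abundance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import CountMatrix, ExpressionMatrix


def compute_fpkm(counts: CountMatrix, stages: pd.Series | None = None) -> ExpressionMatrix:
    """FPKM_gs = c_gs * 1e9 / (L_g * T_s).

    Uses the mapped-read totals supplied with the counts (column sums are
    the fallback recorded at construction time).
    """
    lengths = counts.gene_lengths.to_numpy(dtype=float)
    totals = counts.totals.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if (totals <= 0).any():
        raise ValueError("per-sample totals must be positive")
    c = counts.values.to_numpy(dtype=float)
    fpkm = c * 1e9 / (lengths[:, None] * totals[None, :])
    values = pd.DataFrame(fpkm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values=values, kind="fpkm", stages=stages)


def filter_low_expression(expr: ExpressionMatrix, threshold: float = 1.0
                          ) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose maximum FPKM across samples is strictly below
    ``threshold``; a row with max exactly at the threshold is retained.

    Returns the filtered matrix and the list of removed gene ids.
    """
    if expr.kind != "fpkm":
        raise ValueError("low-expression filter expects an FPKM matrix")
    maxima = expr.values.max(axis=1)
    keep = maxima >= threshold
    removed = list(expr.values.index[~keep])
    if not keep.any():
        raise ValueError(
            f"all {len(removed)} genes fall below max-FPKM {threshold}; "
            "nothing left to analyse")
    out = ExpressionMatrix(values=expr.values.loc[keep].copy(), kind="fpkm",
                           stages=expr.stages)
    return out, removed


def mean_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene's row by its mean across samples (row means -> 1)."""
    means = expr.values.mean(axis=1)
    zero = means[means <= 0]
    if len(zero):
        raise ValueError(f"zero-mean gene(s), e.g. {zero.index[0]!r}; "
                         "filter before normalizing")
    values = expr.values.div(means, axis=0)
    return ExpressionMatrix(values=values, kind="mean_normalized", stages=expr.stages)


def subset_gene_class(expr: ExpressionMatrix, gene_class: set[str]
                      ) -> tuple[ExpressionMatrix, int]:
    """Restrict rows to a gene class (e.g. DNA-binding proteins from PFAM
    annotations), preserving row order. Returns the subset matrix and the
    intersection size.
    """
    if not gene_class:
        raise ValueError("gene_class must be non-empty")
    mask = expr.values.index.isin(gene_class)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("gene class shares no genes with the matrix")
    out = ExpressionMatrix(values=expr.values.loc[mask].copy(), kind=expr.kind,
                           stages=expr.stages)
    return out, n
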