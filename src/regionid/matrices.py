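"""Expression containers: raw counts and normalized expression matrices.

Both containers are thin wrappers around pandas objects so that gene and
sample identifiers travel with the numbers. ``CountMatrix`` carries the
per-transcript lengths and per-sample mapped-read totals needed for FPKM;
``ExpressionMatrix`` carries the stage label of each sample and a ``kind``
flag recording which normalization produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts.

    Attributes
    ----------
    values : DataFrame, genes x samples, non-negative integers.
    gene_lengths : Series indexed by gene id, transcript length in bp.
    totals : Series indexed by sample id, mapped reads per sample.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series
    totals: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if (v.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.gene_lengths.index.equals(v.index):
            self.gene_lengths = self.gene_lengths.reindex(v.index)
        if self.gene_lengths.isna().any():
            raise ValueError("every gene needs a transcript length")
        if (self.gene_lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if not self.totals.index.equals(v.columns):
            self.totals = self.totals.reindex(v.columns)
        if self.totals.isna().any():
            raise ValueError("every sample needs a mapped-read total")
        if (self.totals <= 0).any():
            raise ValueError("per-sample totals must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative real expression values.

    ``kind`` is ``"fpkm"`` or ``"mean_normalized"``; ``stages`` maps each
    sample to its differentiation stage (may be absent for stage-free use).
    """

    values: pd.DataFrame
    kind: str
    stages: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in ("fpkm", "mean_normalized"):
            raise ValueError(f"unknown expression kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.stages is not None and not self.stages.index.equals(self.values.columns):
            self.stages = self.stages.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values.to_numpy(), dtype=float)
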