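"""Figure-style outputs: stage-program heatmaps and their TSV sidecars.

Heatmaps show the top-loading genes of each program, rows blocked by
program in stage order and min-max scaled to [0, 1] for display. Every
rendered image is accompanied by a TSV sidecar holding the plotted
values — the sidecar, not the pixels, is the testable artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StageDesign
from .factorization import ExpressionProgram, Factorization
from .matrices import ExpressionMatrix


@dataclass
class HeatmapSpec:
    values: pd.DataFrame          # rows: genes, columns: samples, scaled [0,1]
    raw_values: pd.DataFrame      # unscaled mean-normalized expression
    row_programs: list[int] = field(default_factory=list)
    row_stages: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("scaled heatmap values must lie in [0, 1]")


def _minmax_rows(df: pd.DataFrame) -> pd.DataFrame:
    lo = df.min(axis=1)
    span = df.max(axis=1) - lo
    span = span.replace(0, 1.0)  # constant rows map to 0
    return df.sub(lo, axis=0).div(span, axis=0)


def build_program_heatmap(expr: ExpressionMatrix, fact: Factorization,
                          programs: list[ExpressionProgram],
                          design: StageDesign, top_n: int = 10) -> HeatmapSpec:
    """Top ``top_n`` member genes per program by loading, blocked by
    program in stage order, columns grouped by stage, rows scaled [0,1].
    """
    gidx = {g: i for i, g in enumerate(fact.gene_ids)}
    stage_rank = {s: i for i, s in enumerate(design.stages)}
    ordered_programs = sorted(
        programs, key=lambda p: stage_rank.get(p.assigned_stage, len(stage_rank)))

    rows: list[str] = []
    row_programs: list[int] = []
    row_stages: list[str | None] = []
    for prog in ordered_programs:
        members = [g for g in prog.member_genes if g in gidx and g in expr.values.index]
        if top_n > len(members):
            warnings.warn(
                f"program {prog.program_index}: top_n={top_n} exceeds "
                f"{len(members)} members; taking all")
        picked = sorted(members, key=lambda g: -fact.W[gidx[g], prog.program_index])
        for g in picked[:top_n]:
            if g not in rows:
                rows.append(g)
                row_programs.append(prog.program_index)
                row_stages.append(prog.assigned_stage)

    columns = [s for stage in design.stages for s in design.samples_of(stage)]
    raw = expr.values.loc[rows, columns]
    return HeatmapSpec(values=_minmax_rows(raw), raw_values=raw,
                       row_programs=row_programs, row_stages=row_stages)


def render(spec: HeatmapSpec, path) -> tuple[Path, Path]:
    """Write the heatmap image (PNG) and its TSV sidecar.

    Returns (image_path, sidecar_path). The sidecar holds the scaled
    values at full float precision and round-trips exactly.
    """
    if spec.values.empty:
        raise ValueError("empty heatmap spec; nothing to render")
    path = Path(path)
    sidecar = path.with_suffix(".tsv")
    spec.values.to_csv(sidecar, sep="\t", index_label="gene_id",
                       float_format="%.17g")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * spec.values.shape[1]),
                 max(3, 0.18 * spec.values.shape[0])))
    ax.imshow(spec.values.to_numpy(), aspect="auto", cmap="viridis",
              vmin=0, vmax=1, interpolation="nearest")
    ax.set_xticks(np.arange(spec.values.shape[1]))
    ax.set_xticklabels(spec.values.columns, rotation=90, fontsize=6)
    ax.set_yticks(np.arange(spec.values.shape[0]))
    ax.set_yticklabels(spec.values.index, fontsize=5)
    ax.set_xlabel("sample")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path, sidecar
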