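"""Readers and writers for the plain-text formats used across the pipeline.

Counts, lengths and sample tables are TSV; gene sets are GMT (name,
description, then tab-separated gene ids); truth and factorization
metadata are JSON. Floating-point matrices are printed at 6 significant
digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .design import StageDesign, generate_design
from .matrices import CountMatrix, ExpressionMatrix

FLOAT_FMT = "%.6g"


def write_counts(counts: CountMatrix, counts_path, lengths_path, samples_path,
                 design: StageDesign | None = None) -> None:
    counts.values.to_csv(counts_path, sep="\t", index_label="gene_id")
    counts.gene_lengths.rename("length").to_csv(
        lengths_path, sep="\t", index_label="gene_id")
    if design is not None:
        stage_of = design.stage_of()
        table = pd.DataFrame({
            "sample_id": counts.sample_ids,
            "stage": [stage_of[s] for s in counts.sample_ids],
        })
    else:
        table = pd.DataFrame({"sample_id": counts.sample_ids, "stage": "NA"})
    table.to_csv(samples_path, sep="\t", index=False)


def read_counts(counts_path, lengths_path, samples_path=None
                ) -> tuple[CountMatrix, StageDesign | None]:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    totals = values.sum(axis=0)
    design = None
    if samples_path is not None:
        table = pd.read_csv(samples_path, sep="\t")
        stages: list[str] = []
        reps: list[int] = []
        for st in table["stage"]:
            if not stages or stages[-1] != st:
                stages.append(st)
                reps.append(1)
            else:
                reps[-1] += 1
        design = generate_design(stages, reps)
    cm = CountMatrix(values=values, gene_lengths=lengths, totals=totals.astype(float))
    return cm, design


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id",
                       float_format=FLOAT_FMT)


def read_expression(path, kind: str, stages: pd.Series | None = None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, kind=kind, stages=stages)


def read_sample_table(path) -> pd.Series:
    """Read a (sample_id, stage) TSV into a Series indexed by sample."""
    table = pd.read_csv(path, sep="\t")
    return pd.Series(table["stage"].to_numpy(), index=table["sample_id"], name="stage")


# ---------------------------------------------------------------- GMT ----

def write_gmt(sets: dict[str, set[str] | list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            out[fields[0]] = set(fields[2:])
    return out


# --------------------------------------------------------------- JSON ----

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
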