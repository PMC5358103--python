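"""End-to-end pipeline: counts -> FPKM -> filter -> mean-normalize ->
replicated NMF -> programs -> hypergeometric enrichment -> reports.

All randomness flows from ``base_seed``; a rerun with the same config is
bit-identical. Every intermediate is written to the output directory
together with a manifest of parameters and seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io
from .design import StageDesign
from .enrichment import GeneSet, enrich, results_table
from .factorization import (Factorization, assign_program_stages,
                            extract_programs, nnmf_replicates)
from .matrices import CountMatrix
from .normalization import compute_fpkm, filter_low_expression, mean_normalize
from .reporting import build_program_heatmap, render

log = logging.getLogger("regionid")


@dataclass
class PipelineConfig:
    out_dir: str = "regionid_out"
    fpkm_threshold: float = 1.0
    k: int | None = None              # default: number of stages
    n_replicates: int = 10
    sd_multiplier: float = 2.0
    sd_kind: str = "population"       # or "sample"
    tol: float = 1e-6
    max_iter: int = 2000
    base_seed: int = 0
    objective: str = "frobenius"      # or "kl"
    bh_correction: bool = False
    min_set_size: int = 10
    heatmap_top_n: int = 10
    universe: str = "filtered"        # or "filtered_and_sets"

    def validate(self) -> None:
        if self.fpkm_threshold < 0:
            raise ValueError("fpkm_threshold must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.objective not in ("frobenius", "kl"):
            raise ValueError("objective must be frobenius or kl")
        if self.sd_kind not in ("population", "sample"):
            raise ValueError("sd_kind must be population or sample")
        if self.universe not in ("filtered", "filtered_and_sets"):
            raise ValueError("universe must be filtered or filtered_and_sets")


@dataclass
class PipelineResult:
    fpkm: object
    filtered: object
    removed_genes: list[str]
    normalized: object
    factorization: Factorization
    replicate_log: list[tuple[int, float]]
    programs: list
    enrichment: pd.DataFrame | None
    out_dir: Path = field(default_factory=Path)


def run_pipeline(counts: CountMatrix, design: StageDesign,
                 gene_sets: dict[str, set[str]] | None = None,
                 config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("config: %s", asdict(config))

    k = config.k if config.k is not None else design.n_stages
    if k > design.n_samples:
        raise ValueError(
            f"[factorize] rank k={k} exceeds sample count {design.n_samples}")

    stage_series = pd.Series(design.stage_of()).reindex(counts.sample_ids)

    log.info("[normalize] FPKM on %d genes x %d samples", *counts.shape)
    fpkm = compute_fpkm(counts, stages=stage_series)
    filtered, removed = filter_low_expression(fpkm, config.fpkm_threshold)
    log.info("[normalize] filter max-FPKM<%g removed %d genes, %d retained",
             config.fpkm_threshold, len(removed), filtered.shape[0])
    normalized = mean_normalize(filtered)

    io.write_expression(fpkm, out / "fpkm.tsv")
    io.write_expression(normalized, out / "normalized.tsv")
    (out / "removed_genes.txt").write_text("\n".join(removed) + "\n" if removed else "")

    log.info("[factorize] k=%d, %d replicates, seeds %d..%d", k,
             config.n_replicates, config.base_seed,
             config.base_seed + config.n_replicates - 1)
    fact, rep_log = nnmf_replicates(
        normalized, k, n_replicates=config.n_replicates,
        base_seed=config.base_seed, max_iter=config.max_iter, tol=config.tol,
        objective=config.objective)
    for seed, obj in rep_log:
        log.info("[factorize]   seed %d -> objective %.6g%s", seed, obj,
                 "  (selected)" if seed == fact.seed else "")
    pd.DataFrame(rep_log, columns=["seed", "objective"]).to_csv(
        out / "replicates.tsv", sep="\t", index=False)
    pd.DataFrame(fact.W, index=fact.gene_ids).to_csv(
        out / "W.tsv", sep="\t", index_label="gene_id", float_format="%.6g")
    pd.DataFrame(fact.H, columns=fact.sample_ids).to_csv(
        out / "H.tsv", sep="\t", index_label="program", float_format="%.6g")

    programs = extract_programs(fact, sd_multiplier=config.sd_multiplier,
                                sd_kind=config.sd_kind)
    programs = assign_program_stages(fact, design, programs)
    io.write_gmt({f"program_{p.program_index}_{p.assigned_stage}":
                  p.member_genes for p in programs}, out / "programs.gmt")
    io.write_json({
        "programs": [{
            "index": p.program_index, "stage": p.assigned_stage,
            "threshold": p.threshold, "size": len(p.member_genes),
            "non_specific": p.non_specific,
        } for p in programs],
        "objective": fact.objective, "seed": fact.seed, "k": fact.k,
    }, out / "programs.json")

    enr_df = None
    if gene_sets:
        universe = set(normalized.gene_ids)
        if config.universe == "filtered_and_sets":
            all_set_genes = set().union(*gene_sets.values())
            universe |= all_set_genes & set(normalized.gene_ids)
        log.info("[enrich] universe size %d, %d sets", len(universe), len(gene_sets))
        sets = [GeneSet(name=n, genes=frozenset(g)) for n, g in gene_sets.items()]
        results = enrich(programs, sets, universe, min_set_size=config.min_set_size)
        enr_df = results_table(results, bh_correction=config.bh_correction)
        enr_df.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")

    spec = build_program_heatmap(normalized, fact, programs, design,
                                 top_n=config.heatmap_top_n)
    render(spec, out / "program_heatmap.png")

    io.write_json({"config": asdict(config), "selected_seed": fact.seed,
                   "objective": fact.objective,
                   "n_genes_retained": int(normalized.shape[0])},
                  out / "manifest.json")
    return PipelineResult(fpkm=fpkm, filtered=filtered, removed_genes=removed,
                          normalized=normalized, factorization=fact,
                          replicate_log=rep_log, programs=programs,
                          enrichment=enr_df, out_dir=out)
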