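"""Synthetic stage-structured RNA-seq data with planted expression programs.

The generator emulates the structure of a staged differentiation
experiment: a handful of stages (ES, DE, and day-5/7/10 organoids) with a
few replicates each, a genome-scale gene list, and for each stage a
disjoint block of genes up-regulated by a known fold change in that
stage's samples only. Counts follow a negative binomial (the standard
bulk RNA-seq noise model; a lognormal alternative is available), gene
lengths are uniform over a stated range so the FPKM length correction is
actually exercised, and per-sample library sizes vary lognormally so the
depth correction is exercised too.

Because the planted programs are known, every downstream stage —
normalization, factorization, program extraction, enrichment — can be
checked against ground truth without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import StageDesign, generate_design
from .matrices import CountMatrix

DEFAULT_STAGES = ("ES", "DE", "OD5", "OD7", "OD10")
DEFAULT_LENGTH_RANGE = (500, 5000)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic bundle.

    ``program_genes`` maps each stage to the (pairwise disjoint) set of
    genes planted as up-regulated by ``fold_change`` in that stage.
    """

    program_genes: dict[str, frozenset[str]]
    fold_change: float
    baseline_mean: float
    dispersion: float
    seed: int

    def __post_init__(self) -> None:
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        sets = list(self.program_genes.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("planted program sets must be disjoint")

    def as_dict(self) -> dict:
        return {
            "program_genes": {k: sorted(v) for k, v in self.program_genes.items()},
            "fold_change": self.fold_change,
            "baseline_mean": self.baseline_mean,
            "dispersion": self.dispersion,
            "seed": self.seed,
        }


@dataclass
class SyntheticBundle:
    counts: CountMatrix
    design: StageDesign
    truth: PlantedTruth
    literature_sets: dict[str, set[str]] = field(default_factory=dict)
    qpcr_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        genes = set(self.counts.gene_ids)
        for stage, members in self.truth.program_genes.items():
            if not members <= genes:
                raise ValueError(f"planted genes for {stage} missing from counts")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # var = mu + dispersion * mu^2  (gamma-Poisson with shape 1/dispersion)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(design: StageDesign | None = None,
                    n_genes: int = 2000,
                    program_size: int = 200,
                    fold_change: float = 8.0,
                    baseline_mean: float = 50.0,
                    dispersion: float = 0.1,
                    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
                    libsize_sigma: float = 0.2,
                    count_model: str = "nb",
                    seed: int = 0) -> SyntheticBundle:
    """Simulate a count matrix with one planted program per stage.

    Background genes have expected expression ``baseline_mean`` in every
    sample; each stage's planted genes have ``baseline_mean*fold_change``
    in that stage's samples. Per-sample lognormal size factors (sigma
    ``libsize_sigma``) scale all means of a sample. Per-sample totals are
    recorded as the column sums. Deterministic under a fixed seed.
    """
    if design is None:
        design = generate_design(DEFAULT_STAGES, 3)
    if n_genes < design.n_stages * program_size:
        raise ValueError("n_genes must fit one program per stage")
    if program_size <= 0 or baseline_mean <= 0 or dispersion <= 0:
        raise ValueError("program_size, baseline_mean and dispersion must be positive")
    if fold_change <= 1:
        raise ValueError("fold_change must exceed 1")
    if count_model not in ("nb", "lognormal"):
        raise ValueError(f"unknown count model {count_model!r}")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids = list(design.sample_ids)
    stage_of = design.stage_of()

    # disjoint planted blocks at the head of the gene list
    program_genes: dict[str, frozenset[str]] = {}
    for s_idx, stage in enumerate(design.stages):
        block = gene_ids[s_idx * program_size:(s_idx + 1) * program_size]
        program_genes[stage] = frozenset(block)

    mean = np.full((n_genes, design.n_samples), baseline_mean)
    for s_idx, stage in enumerate(design.stages):
        rows = slice(s_idx * program_size, (s_idx + 1) * program_size)
        cols = [j for j, sid in enumerate(sample_ids) if stage_of[sid] == stage]
        mean[rows, cols] *= fold_change

    size_factors = rng.lognormal(0.0, libsize_sigma, design.n_samples)
    mean = mean * size_factors[None, :]

    if count_model == "nb":
        values = _nb_draw(rng, mean, dispersion)
    else:
        # lognormal alternative: match mean and a comparable CV
        sigma2 = np.log1p(dispersion)
        draw = rng.lognormal(np.log(mean) - sigma2 / 2, np.sqrt(sigma2))
        values = np.round(draw).astype(int)

    lengths = rng.integers(length_range[0], length_range[1] + 1, n_genes)
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    counts = CountMatrix(
        values=df,
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        totals=df.sum(axis=0).astype(float),
    )
    truth = PlantedTruth(program_genes=program_genes, fold_change=fold_change,
                         baseline_mean=baseline_mean, dispersion=dispersion,
                         seed=seed)
    return SyntheticBundle(counts=counts, design=design, truth=truth)


def generate_literature_sets(truth: PlantedTruth,
                             universe: list[str],
                             match_fraction: float = 0.5,
                             decoy_size: int = 200,
                             seed: int = 0) -> dict[str, set[str]]:
    """Literature-style gene sets with controlled overlap to the truth.

    For each stage, a ``matched_<stage>`` set keeps ``match_fraction`` of
    the planted program and is padded with random fillers (drawn from the
    rest of the universe, so chance collisions with planted genes are
    possible) up to ``decoy_size``; one extra ``decoy_colon`` set is drawn
    entirely from non-planted genes, disjoint from every program — the
    negative control mirroring a colonic gene set that no stage program
    should hit. At ``match_fraction`` 0 the matched sets are plain uniform
    draws from the universe, giving an exact enrichment null.
    """
    if not 0 <= match_fraction <= 1:
        raise ValueError("match_fraction must lie in [0, 1]")
    if decoy_size > len(universe):
        raise ValueError("decoy_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    planted_all = set().union(*truth.program_genes.values())
    nonplanted = sorted(set(universe) - planted_all)

    sets: dict[str, set[str]] = {}
    for stage, members in truth.program_genes.items():
        members_in = sorted(members & set(universe))
        n_keep = int(round(match_fraction * len(members_in)))
        kept = list(rng.choice(members_in, n_keep, replace=False)) if n_keep else []
        pool = sorted(set(universe) - set(kept))
        n_fill = max(decoy_size - len(kept), 0)
        if n_fill > len(pool):
            raise ValueError("not enough genes in the universe for fillers")
        fillers = list(rng.choice(pool, n_fill, replace=False))
        sets[f"matched_{stage}"] = set(kept) | set(fillers)

    if decoy_size > len(nonplanted):
        raise ValueError("not enough non-planted genes for the decoy set")
    sets["decoy_colon"] = set(rng.choice(nonplanted, decoy_size, replace=False))
    return sets


def generate_qpcr(regions: list[str],
                  genes: list[str],
                  gradient: dict[str, dict[str, float]],
                  noise_sd: float = 0.25,
                  n_per_region: int = 5,
                  n_technical: int = 3,
                  housekeeping_ct: float = 20.0,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate a qRT-PCR Ct table with a planted regional gradient.

    ``gradient[gene][region]`` is the expected delta-Ct (housekeeping
    minus gene); the measured gene Ct is ``housekeeping_ct - delta_ct``
    plus Gaussian noise per technical replicate. The housekeeping Ct is
    held fixed so all variance sits in the gene channel.
    """
    if not regions or not genes:
        raise ValueError("regions and genes must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        for b in range(n_per_region):
            sample_id = f"{region}_s{b + 1}"
            for gene in genes:
                dct = gradient.get(gene, {}).get(region, 0.0)
                for t in range(n_technical):
                    ct = housekeeping_ct - dct + rng.normal(0.0, noise_sd)
                    rows.append({
                        "sample_id": sample_id,
                        "group": region,
                        "gene": gene,
                        "replicate": t + 1,
                        "gene_ct": ct,
                        "housekeeping_ct": housekeeping_ct,
                    })
    return pd.DataFrame(rows)
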