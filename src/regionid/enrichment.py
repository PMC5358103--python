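"""Hypergeometric over-representation of programs in literature gene sets.

For a universe of N genes containing a K-gene literature set, an n-gene
program overlapping the set in x genes is scored by the upper tail
P(X >= x) of the Hypergeometric(N, K, n) distribution — the chance of at
least that much overlap if the program were a random draw from the
universe. Raw p-values are reported (Benjamini-Hochberg adjustment is an
optional extra column); sets below a minimum size are flagged rather
than silently excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .factorization import ExpressionProgram
from .matrices import ExpressionMatrix


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    program_index: int
    assigned_stage: str | None
    set_name: str
    x: int          # overlap
    n: int          # program size
    K: int          # set size after universe restriction
    N: int          # universe size
    p_value: float
    overlapping_genes: frozenset[str]
    small_set: bool = False


def hypergeom_upper_tail(x: int, n: int, K: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), upper tail convention.

    Computed via the survival function in log space for numerical
    stability at extreme overlaps.
    """
    if not (0 <= x <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent arguments x={x}, n={n}, K={K}, N={N}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(programs: list[ExpressionProgram], sets: list[GeneSet],
           universe: set[str], min_set_size: int = 10) -> list[EnrichmentResult]:
    """Score every (program, set) pair against the given universe.

    Sets are restricted to the universe before counting; programs whose
    members fall outside the universe indicate a universe-construction
    bug and raise. Results are sorted by p-value within each program.
    """
    if not programs or not sets:
        raise ValueError("programs and sets must be non-empty")
    N = len(universe)
    results: list[EnrichmentResult] = []
    for prog in programs:
        members = set(prog.member_genes)
        if not members <= universe:
            missing = sorted(members - universe)[:3]
            raise ValueError(
                f"program {prog.program_index} members outside universe "
                f"(e.g. {missing}); rebuild the universe")
        per_prog = []
        for gs in sets:
            restricted = set(gs.genes) & universe
            overlap = members & restricted
            p = hypergeom_upper_tail(len(overlap), len(members), len(restricted), N)
            per_prog.append(EnrichmentResult(
                program_index=prog.program_index,
                assigned_stage=prog.assigned_stage,
                set_name=gs.name, x=len(overlap), n=len(members),
                K=len(restricted), N=N, p_value=p,
                overlapping_genes=frozenset(overlap),
                small_set=len(restricted) < min_set_size))
        per_prog.sort(key=lambda r: r.p_value)
        results.extend(per_prog)
    return results


def results_table(results: list[EnrichmentResult], bh_correction: bool = False
                  ) -> pd.DataFrame:
    """Tabulate enrichment results; optionally add a BH-adjusted column."""
    df = pd.DataFrame([{
        "program": r.program_index,
        "stage": r.assigned_stage,
        "set": r.set_name,
        "overlap": r.x,
        "program_size": r.n,
        "set_size": r.K,
        "universe": r.N,
        "p_value": r.p_value,
        "small_set": r.small_set,
    } for r in results])
    if bh_correction and len(df):
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            rank = m - rank_from_top
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        df["p_adj_bh"] = adj
    return df


def overlap_table(programs: list[ExpressionProgram], sets: list[GeneSet],
                  expr: ExpressionMatrix, W: np.ndarray | None = None,
                  gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Expression of program-by-set overlapping genes, for heatmap rendering.

    Rows are the overlapping genes of each (program, set) pair, blocked
    by program and ordered by loading (descending) when W is available;
    values are the mean-normalized expression from ``expr``.
    """
    loading_of = {}
    if W is not None and gene_ids is not None:
        gidx = {g: i for i, g in enumerate(gene_ids)}
    rows: list[str] = []
    seen: set[str] = set()
    for prog in programs:
        overlap: set[str] = set()
        for gs in sets:
            overlap |= set(prog.member_genes) & set(gs.genes)
        overlap &= set(expr.gene_ids)
        if W is not None and gene_ids is not None:
            ordered = sorted(overlap,
                             key=lambda g: -W[gidx[g], prog.program_index])
            for g in ordered:
                loading_of[g] = W[gidx[g], prog.program_index]
        else:
            ordered = sorted(overlap)
        for g in ordered:
            if g not in seen:
                rows.append(g)
                seen.add(g)
    if not rows:
        import warnings
        warnings.warn("no overlapping genes; overlap table is empty")
        return expr.values.iloc[0:0]
    return expr.values.loc[rows]
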