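"""Non-negative matrix factorization and expression-program extraction.

The mean-normalized expression matrix V (genes x samples) is factored as
V ~ W H with W (genes x k) and H (k x samples) non-negative, using
Lee-Seung multiplicative updates on the squared Frobenius objective
||V - WH||_F^2 (a KL-divergence objective is available behind a flag).
The factorization is restarted from several random seeds and the lowest
reconstruction error is kept as the dictionary of programs.

Each column of W defines a gene expression program: a gene is a member
if its loading strictly exceeds the column mean plus ``sd_multiplier``
standard deviations (default 2). Programs are assigned to the
differentiation stage where their H coefficients are on average highest,
and flagged non-specific when the top stage does not clearly dominate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import StageDesign
from .matrices import ExpressionMatrix

_EPS = 1e-10


@dataclass
class Factorization:
    """Result of one NMF run.

    ``objective_trace`` records the objective after every update sweep;
    multiplicative updates guarantee it is non-increasing.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    objective: float
    n_iter: int
    seed: int
    converged: bool
    objective_trace: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("factor matrices must be non-negative")
        diffs = np.diff(self.objective_trace)
        if (diffs > 1e-9 * max(self.objective_trace[0], 1.0)).any():
            raise ValueError("objective trace increased; update rule broken")


@dataclass(frozen=True)
class ExpressionProgram:
    program_index: int
    member_genes: frozenset[str]
    threshold: float
    assigned_stage: str | None = None
    non_specific: bool = False


def _frobenius_updates(V, W, H, max_iter, tol):
    trace = [float(np.linalg.norm(V - W @ H) ** 2)]
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(V - W @ H) ** 2)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return W, H, trace, converged


def _kl_updates(V, W, H, max_iter, tol):
    def kl(A, B):
        B = B + _EPS
        mask = A > 0
        return float(np.sum(A[mask] * np.log(A[mask] / B[mask])) - A.sum() + B.sum())

    trace = [kl(V, W @ H)]
    converged = False
    for _ in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        obj = kl(V, W @ H)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break
    return W, H, trace, converged


def nnmf(V: ExpressionMatrix | np.ndarray, k: int, max_iter: int = 2000,
         tol: float = 1e-6, seed: int = 0, objective: str = "frobenius"
         ) -> Factorization:
    """Factor V into k non-negative programs by multiplicative updates.

    Initialization is uniform random, scaled so the initial product WH
    matches V's mean. Stops when the relative objective decrease falls
    below ``tol`` or after ``max_iter`` sweeps.
    """
    if isinstance(V, ExpressionMatrix):
        gene_ids, sample_ids = V.gene_ids, V.sample_ids
        A = V.to_array()
    else:
        A = np.asarray(V, dtype=float)
        gene_ids = [f"g{i}" for i in range(A.shape[0])]
        sample_ids = [f"s{j}" for j in range(A.shape[1])]
    if (A < 0).any():
        raise ValueError("V must be non-negative")
    m, n = A.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"rank k={k} must satisfy 1 <= k <= min{(m, n)}")
    if objective not in ("frobenius", "kl"):
        raise ValueError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(A.mean(), _EPS) / k)
    W = rng.uniform(0, 1, (m, k)) * scale
    H = rng.uniform(0, 1, (k, n)) * scale
    step = _frobenius_updates if objective == "frobenius" else _kl_updates
    W, H, trace, converged = step(A, W, H, max_iter, tol)
    return Factorization(W=W, H=H, k=k, objective=trace[-1],
                         n_iter=len(trace) - 1, seed=seed, converged=converged,
                         objective_trace=np.asarray(trace),
                         gene_ids=gene_ids, sample_ids=sample_ids)


def nnmf_replicates(V: ExpressionMatrix | np.ndarray, k: int,
                    n_replicates: int = 10, base_seed: int = 0,
                    max_iter: int = 2000, tol: float = 1e-6,
                    objective: str = "frobenius"
                    ) -> tuple[Factorization, list[tuple[int, float]]]:
    """Run ``n_replicates`` restarts (seeds base_seed..base_seed+n-1) and
    keep the factorization with the lowest reconstruction error; ties go
    to the lowest seed. Returns (best, [(seed, objective), ...]).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    best: Factorization | None = None
    log: list[tuple[int, float]] = []
    for seed in range(base_seed, base_seed + n_replicates):
        fact = nnmf(V, k, max_iter=max_iter, tol=tol, seed=seed, objective=objective)
        log.append((seed, fact.objective))
        if best is None or fact.objective < best.objective:
            best = fact
    assert best is not None
    return best, log


def extract_programs(fact: Factorization, sd_multiplier: float = 2.0,
                     sd_kind: str = "population") -> list[ExpressionProgram]:
    """Membership rule: loading strictly above mean + sd_multiplier * SD
    of the program's loading column. A degenerate all-equal column has SD
    zero, so the strict inequality yields an empty program.
    """
    if sd_kind not in ("population", "sample"):
        raise ValueError(f"unknown sd_kind {sd_kind!r}")
    ddof = 0 if sd_kind == "population" else 1
    programs = []
    genes = np.asarray(fact.gene_ids)
    for j in range(fact.k):
        col = fact.W[:, j]
        threshold = float(col.mean() + sd_multiplier * col.std(ddof=ddof))
        members = frozenset(genes[col > threshold])
        programs.append(ExpressionProgram(program_index=j, member_genes=members,
                                          threshold=threshold))
    return programs


def assign_program_stages(fact: Factorization, design: StageDesign,
                          programs: list[ExpressionProgram] | None = None,
                          specificity_ratio: float = 2.0
                          ) -> list[ExpressionProgram]:
    """Assign each program the stage with the highest mean H coefficient.

    A program whose top stage mean is below ``specificity_ratio`` times
    the runner-up's mean is flagged non-specific. Returns programs with
    stages filled in (extracting them first if not supplied).
    """
    if list(design.sample_ids) != list(fact.sample_ids):
        raise ValueError("design samples do not match factorization columns")
    if programs is None:
        programs = extract_programs(fact)
    sample_ids = list(fact.sample_ids)
    stage_of = design.stage_of()
    stage_cols = {stage: [i for i, s in enumerate(sample_ids) if stage_of[s] == stage]
                  for stage in design.stages}
    out = []
    for prog in programs:
        means = {stage: float(fact.H[prog.program_index, cols].mean())
                 for stage, cols in stage_cols.items()}
        ranked = sorted(means.items(), key=lambda kv: -kv[1])
        top_stage, top = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0.0
        non_specific = top < specificity_ratio * second
        out.append(ExpressionProgram(program_index=prog.program_index,
                                     member_genes=prog.member_genes,
                                     threshold=prog.threshold,
                                     assigned_stage=top_stage,
                                     non_specific=non_specific))
    return out
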