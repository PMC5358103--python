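"""qRT-PCR arbitrary-units quantification and group comparison statistics.

Relative expression is reported in arbitrary units,

    AU = 2^(housekeeping Ct - gene Ct) * 10,000,

so a gene amplifying at the housekeeping gene's cycle reads exactly
10,000 and each extra cycle halves the value. Technical replicates are
averaged on the AU (linear) scale. Groups (intestinal regions or
organoid conditions) are compared with classical one-way ANOVA, or an
unpaired pooled-variance t-test for two-group designs, and annotated
with the conventional significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def arbitrary_units(gene_ct, housekeeping_ct):
    """AU = 2^(housekeeping_ct - gene_ct) * 10000; vectorized."""
    gene_ct = np.asarray(gene_ct, dtype=float)
    housekeeping_ct = np.asarray(housekeeping_ct, dtype=float)
    if not (np.isfinite(gene_ct).all() and np.isfinite(housekeeping_ct).all()):
        raise ValueError("Ct values must be finite")
    au = np.exp2(housekeeping_ct - gene_ct) * 10_000.0
    return float(au) if au.ndim == 0 else au


def collapse_technical_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the AU scale per (sample, gene).

    Expects columns sample_id, group, gene, gene_ct, housekeeping_ct
    (replicate optional). Rows with missing Ct are dropped and counted in
    an ``n_missing`` column.
    """
    df = records.copy()
    missing = df["gene_ct"].isna() | df["housekeeping_ct"].isna()
    df = df.loc[~missing].copy()
    df["au"] = arbitrary_units(df["gene_ct"], df["housekeeping_ct"])
    n_missing = (records.assign(_miss=missing)
                 .groupby(["sample_id", "gene"], sort=False)["_miss"].sum())
    out = (df.groupby(["sample_id", "group", "gene"], sort=False)
             .agg(au=("au", "mean"), n_technical=("au", "size"))
             .reset_index())
    out["n_missing"] = out.set_index(["sample_id", "gene"]).index.map(n_missing).astype(int)
    return out


def one_way_anova(groups: list[np.ndarray | list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within, df (k-1, N-k)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    flat = np.concatenate(arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_between = sum(len(a) * (a.mean() - flat.mean()) ** 2 for a in arrays)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("all observations identical; F undefined")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def unpaired_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test, pooled variance by default (Welch behind a flag)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if not welch and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance; t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    for cutoff, stars in STAR_THRESHOLDS:
        if p < cutoff:
            return stars
    return ""


@dataclass(frozen=True)
class GroupSummary:
    group: str
    gene: str
    n: int
    mean_au: float
    sem_au: float | None
    median_au: float


def summarize_groups(collapsed: pd.DataFrame, test: str = "anova"
                     ) -> tuple[list[GroupSummary], pd.DataFrame]:
    """Per-(group, gene) n / mean / sem / median of AU, plus per-gene test.

    ``test`` is "anova" (default) or "ttest" (two groups only). The
    returned frame has one row per gene with the statistic, p-value and
    star annotation. SEM is None for n = 1 groups.
    """
    summaries: list[GroupSummary] = []
    for (group, gene), vals in collapsed.groupby(["group", "gene"], sort=False)["au"]:
        v = vals.to_numpy()
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else None
        summaries.append(GroupSummary(group=group, gene=gene, n=len(v),
                                      mean_au=float(v.mean()), sem_au=sem,
                                      median_au=float(np.median(v))))
    rows = []
    for gene, sub in collapsed.groupby("gene", sort=False):
        groups = [g.to_numpy() for _, g in sub.groupby("group", sort=False)["au"]]
        if test == "anova":
            stat, p = one_way_anova(groups)
        elif test == "ttest":
            if len(groups) != 2:
                raise ValueError("t-test requires exactly two groups")
            stat, p = unpaired_t_test(groups[0], groups[1])
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"gene": gene, "test": test, "statistic": stat,
                     "p_value": p, "stars": significance_stars(p)})
    return summaries, pd.DataFrame(rows)
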