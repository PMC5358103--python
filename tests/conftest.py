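import numpy as np
import pandas as pd
import pytest

import regionid as r


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle: 5 stages x 3 reps, 2000 genes,
    200-gene planted programs, fold change 8, NB dispersion 0.1."""
    return r.generate_counts(seed=0)


@pytest.fixture(scope="session")
def normalized(bundle):
    fpkm = r.compute_fpkm(bundle.counts)
    filtered, _ = r.filter_low_expression(fpkm)
    return r.mean_normalize(filtered)


@pytest.fixture(scope="session")
def factorized(bundle, normalized):
    """Best of 10 NMF replicates at k=5 with stage-assigned programs."""
    fact, rep_log = r.nnmf_replicates(normalized, 5, n_replicates=10, base_seed=0)
    programs = r.assign_program_stages(fact, bundle.design)
    return fact, programs, rep_log


@pytest.fixture
def tiny_counts():
    """Hand-sized count matrix for exact normalization arithmetic."""
    values = pd.DataFrame(
        [[10, 0], [5, 5], [0, 4]],
        index=["gA", "gB", "gC"], columns=["s1", "s2"])
    lengths = pd.Series([1000, 2000, 1500], index=values.index)
    totals = pd.Series([1_000_000.0, 2_000_000.0], index=values.columns)
    return r.CountMatrix(values=values, gene_lengths=lengths, totals=totals)
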