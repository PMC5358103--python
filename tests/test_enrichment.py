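from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import regionid as r
from regionid.enrichment import GeneSet, enrich, hypergeom_upper_tail, results_table


def exact_upper_tail(x, n, K, N):
    """Exact-fraction enumeration oracle: P(X >= x), X ~ Hypergeom(N, K, n)."""
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(x, min(n, K) + 1):
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(acc)


class TestUpperTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_small_case_against_enumeration(self):
        # N=10, K=4, n=3, x=3: C(4,3)/C(10,3) = 4/120
        assert hypergeom_upper_tail(3, 3, 4, 10) == pytest.approx(4 / 120, rel=1e-12)

    def test_moderate_case_against_enumeration(self):
        expected = exact_upper_tail(2, 5, 5, 20)
        assert hypergeom_upper_tail(2, 5, 5, 20) == pytest.approx(expected, rel=1e-12)

    def test_inconsistent_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 3, 11, 10)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.data())
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(1, 20))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        x = data.draw(st.integers(0, n))
        p = hypergeom_upper_tail(x, n, K, N)
        assert p == pytest.approx(exact_upper_tail(x, n, K, N), rel=1e-12, abs=1e-300)

    def test_monotone_non_increasing_in_overlap(self):
        ps = [hypergeom_upper_tail(x, 10, 8, 40) for x in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_duality_in_n_and_K(self):
        for x in range(5):
            assert hypergeom_upper_tail(x, 7, 12, 30) == pytest.approx(
                hypergeom_upper_tail(x, 12, 7, 30), rel=1e-12)


def _program(idx, genes, stage=None):
    return r.ExpressionProgram(program_index=idx, member_genes=frozenset(genes),
                               threshold=0.0, assigned_stage=stage)


class TestEnrich:
    def test_disjoint_set_gives_p_one(self):
        universe = {f"g{i}" for i in range(50)}
        prog = _program(0, {"g0", "g1", "g2"})
        gs = GeneSet(name="other", genes=frozenset({"g10", "g11"}))
        res = enrich([prog], [gs], universe)
        assert res[0].x == 0 and res[0].p_value == 1.0

    def test_saturated_case(self):
        universe = {"a", "b", "c"}
        prog = _program(0, universe)
        gs = GeneSet(name="all", genes=frozenset(universe))
        res = enrich([prog], [gs], universe)
        assert res[0].x == res[0].n == res[0].K == res[0].N == 3
        assert res[0].p_value == 1.0

    def test_member_outside_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            enrich([_program(0, {"zz"})],
                   [GeneSet(name="s", genes=frozenset({"a"}))], {"a", "b"})

    def test_small_sets_flagged(self):
        universe = {f"g{i}" for i in range(30)}
        res = enrich([_program(0, {"g0"})],
                     [GeneSet(name="tiny", genes=frozenset({"g0", "g1"}))],
                     universe, min_set_size=10)
        assert res[0].small_set

    def test_matched_sets_hit_and_decoy_misses(self, bundle, factorized, normalized):
        _, programs, _ = factorized
        sets_dict = r.generate_literature_sets(
            bundle.truth, normalized.gene_ids, match_fraction=0.5,
            decoy_size=200, seed=1)
        sets = [GeneSet(name=n, genes=frozenset(g)) for n, g in sets_dict.items()]
        universe = set(normalized.gene_ids)
        res = enrich(programs, sets, universe)
        by = {(x.program_index, x.set_name): x for x in res}
        for p in programs:
            assert by[(p.program_index, f"matched_{p.assigned_stage}")].p_value < 1e-10
            assert by[(p.program_index, "decoy_colon")].p_value > 0.01

    def test_bh_column_monotone_and_bounded(self):
        universe = {f"g{i}" for i in range(100)}
        progs = [_program(0, {f"g{i}" for i in range(10)})]
        sets = [GeneSet(name=f"s{j}", genes=frozenset({f"g{j * 7 + i}" for i in range(8)}))
                for j in range(5)]
        df = results_table(enrich(progs, sets, universe), bh_correction=True)
        assert (df["p_adj_bh"] >= df["p_value"] - 1e-15).all()
        assert (df["p_adj_bh"] <= 1.0).all()


class TestOverlapTable:
    def test_three_overlapping_genes_give_three_rows(self, normalized):
        genes = list(normalized.gene_ids[:5])
        prog = _program(0, set(genes))
        gs = GeneSet(name="s", genes=frozenset(genes[:3]))
        table = r.overlap_table([prog], [gs], normalized)
        assert table.shape[0] == 3

    def test_rows_ordered_by_loading_within_program(self, bundle, factorized, normalized):
        fact, programs, _ = factorized
        sets_dict = r.generate_literature_sets(
            bundle.truth, normalized.gene_ids, match_fraction=0.5,
            decoy_size=200, seed=1)
        sets = [GeneSet(name=n, genes=frozenset(g)) for n, g in sets_dict.items()]
        table = r.overlap_table(programs, sets, normalized, W=fact.W,
                                gene_ids=fact.gene_ids)
        gidx = {g: i for i, g in enumerate(fact.gene_ids)}
        row_of = {g: i for i, g in enumerate(table.index)}
        for p in programs:
            members = [g for g in table.index if g in p.member_genes]
            members.sort(key=lambda g: row_of[g])
            loadings = [fact.W[gidx[g], p.program_index] for g in members]
            assert all(a >= b - 1e-12 for a, b in zip(loadings, loadings[1:]))

    def test_matched_rows_peak_in_assigned_stage(self, bundle, factorized, normalized):
        fact, programs, _ = factorized
        sets_dict = r.generate_literature_sets(
            bundle.truth, normalized.gene_ids, match_fraction=0.5,
            decoy_size=200, seed=1)
        sets = [GeneSet(name=n, genes=frozenset(g)) for n, g in sets_dict.items()]
        table = r.overlap_table(programs, sets, normalized, W=fact.W,
                                gene_ids=fact.gene_ids)
        n_good = n_tot = 0
        for p in programs:
            in_cols = bundle.design.samples_of(p.assigned_stage)
            out_cols = [s for s in normalized.sample_ids if s not in in_cols]
            for g in table.index:
                if g in p.member_genes:
                    n_tot += 1
                    if (table.loc[g, in_cols].mean() > table.loc[g, out_cols].mean()):
                        n_good += 1
        assert n_good / n_tot >= 0.9

    def test_empty_overlap_warns_and_returns_empty(self, normalized):
        prog = _program(0, {normalized.gene_ids[0]})
        gs = GeneSet(name="s", genes=frozenset({"absent_gene"}))
        with pytest.warns(UserWarning):
            table = r.overlap_table([prog], [gs], normalized)
        assert table.empty
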