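"""Hypergeometric over-representation, BH correction, ranking, candidate genes."""

import pytest
from hypothesis import given, settings, strategies as st

import wesprio as w
from tests.conftest import oracle_bh, oracle_hypergeom_upper


def mkset(set_id, genes, name=""):
    return w.PathwayGeneSet(set_id=set_id, name=name or set_id,
                            genes=frozenset(genes))


def genes(prefix, n):
    return [f"{prefix}{i:04d}" for i in range(n)]


class TestHypergeomEnrich:
    def test_zero_overlap_is_p_one(self):
        bg = genes("g", 100)
        sets = [mkset("S1", bg[:10])]
        (r,) = w.hypergeom_enrich(bg[50:60], sets, background=bg)
        assert r.p_value == 1.0 and r.input_number == 0 and r.rich_factor == 0.0

    def test_input_equals_pathway_equals_background(self):
        bg = genes("g", 12)
        (r,) = w.hypergeom_enrich(bg, [mkset("S1", bg)], background=bg)
        assert r.p_value == pytest.approx(1.0)
        assert r.rich_factor == pytest.approx(1.0)

    def test_large_population_matches_enumeration(self):
        bg = genes("g", 1000)
        sets = [mkset("S1", bg[:50])]
        inp = bg[:10] + bg[500:590]  # 100 draws, overlap 10
        (r,) = w.hypergeom_enrich(inp, sets, background=bg)
        assert r.input_number == 10 and r.background_number == 50
        assert r.p_value == pytest.approx(
            oracle_hypergeom_upper(1000, 50, 100, 10), rel=1e-9
        )
        assert r.rich_factor == pytest.approx(10 / 50)

    @given(
        M=st.integers(10, 400), K=st.integers(1, 100),
        n=st.integers(1, 100), k=st.integers(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, M, K, n, k):
        K, n = min(K, M), min(n, M)
        k = min(k, K, n)
        if k < max(0, K + n - M):
            k = max(0, K + n - M)
        bg = genes("g", M)
        pathway = bg[:K]
        inp = bg[:k] + bg[K:K + (n - k)]
        (r,) = w.hypergeom_enrich(inp, [mkset("S", pathway)], background=bg)
        assert r.p_value == pytest.approx(
            oracle_hypergeom_upper(M, K, n, k), rel=1e-9, abs=1e-12
        )

    def test_out_of_background_input_dropped(self):
        bg = genes("g", 50)
        (r,) = w.hypergeom_enrich(bg[:5] + ["NOT_IN_BG"], [mkset("S", bg[:10])],
                                  background=bg)
        assert r.input_number == 5

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            w.hypergeom_enrich(["a"], [], background=[])

    def test_published_style_rich_factor(self):
        # an overlap of 3 genes in a 50-gene pathway has rich factor 0.06
        bg = genes("g", 500)
        (r,) = w.hypergeom_enrich(bg[:3] + bg[100:117], [mkset("S", bg[:50])],
                                  background=bg)
        assert r.rich_factor == pytest.approx(0.06)


class TestAdjustPvalues:
    def test_hand_computed_bh(self):
        assert w.adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_and_tied_inputs(self):
        assert w.adjust_pvalues([0.2]) == pytest.approx([0.2])
        assert w.adjust_pvalues([0.04, 0.04, 0.04]) == pytest.approx([0.04] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            w.adjust_pvalues([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_hand_bh_and_dominates_raw(self, ps):
        adj = w.adjust_pvalues(ps)
        assert adj == pytest.approx(oracle_bh(ps), rel=1e-12)
        for raw, a in zip(ps, adj):
            assert a >= raw - 1e-15

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariant(self, ps, rnd):
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        adj = w.adjust_pvalues(ps)
        adj_perm = w.adjust_pvalues([ps[i] for i in idx])
        assert adj_perm == pytest.approx([adj[i] for i in idx], rel=1e-12)


class TestRankingAndCandidates:
    def _results(self):
        bg = genes("g", 200)
        sets = [mkset(f"S{i:02d}", bg[i * 5:(i + 1) * 5 + 3]) for i in range(40)]
        return w.hypergeom_enrich(bg[:20], sets, background=bg)

    def test_top_k_truncation(self):
        assert len(w.top_pathways(self._results(), k=30)) == 30

    def test_tie_break_by_raw_p_then_id(self):
        rs = self._results()
        ranked = w.top_pathways(rs, k=len(rs))
        keys = [(r.corrected_p, r.p_value, r.set_id) for r in ranked]
        assert keys == sorted(keys)

    def test_planted_overlap_heavy_pathway_ranks_first(self):
        bg = genes("g", 300)
        inp = bg[:15]
        sets = [mkset("PLANTED", bg[:15])] + [
            mkset(f"N{i:02d}", bg[20 + i * 9: 20 + (i + 1) * 9]) for i in range(20)
        ]
        ranked = w.top_pathways(w.hypergeom_enrich(inp, sets, background=bg))
        assert ranked[0].set_id == "PLANTED"

    def test_select_candidates_union_dedup_alphabetical(self):
        rs = self._results()
        tags = [rs[0].set_id, rs[1].set_id, rs[0].set_id]  # duplicate tag
        out = w.select_candidates(rs, tags)
        expected = sorted(set(rs[0].overlap_genes) | set(rs[1].overlap_genes))
        assert out == expected

    def test_empty_and_unknown_tags(self):
        rs = self._results()
        assert w.select_candidates(rs, []) == []
        assert w.select_candidates(rs, ["NO_SUCH_SET"]) == []
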