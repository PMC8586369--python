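"""Clone-group Mann-Whitney tests, scrambles, and the false-positive score.

Independent oracles used here:

* one-sided Mann-Whitney p by exhaustive enumeration of all C(n, n_a) label
  assignments of the combined sample (tie-free case);
* FPS by the literal double loop over genes and scrambles.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from clonotrx.bridge_map import CellCloneMap
from clonotrx.dge import (
    CloneGroupDGE,
    CloneGrouping,
    call_significant,
    cells_for_groups,
    compute_fps,
    mannwhitney_per_gene,
    scramble_map,
)


def enumeration_pvalue(a, b, direction):
    """Exact one-sided Mann-Whitney p by brute-force enumeration."""
    a, b = list(a), list(b)
    combined = a + b
    n, n_a = len(combined), len(a)

    def u_stat(avals, bvals):
        return sum((x > y) + 0.5 * (x == y) for x in avals for y in bvals)

    u_obs = u_stat(a, b)
    hits = total = 0
    for idx in combinations(range(n), n_a):
        sel = set(idx)
        ua = u_stat([combined[i] for i in idx],
                    [combined[i] for i in range(n) if i not in sel])
        if direction == "a_greater":
            hits += ua >= u_obs
        else:
            hits += ua <= u_obs
        total += 1
    return hits / total


def brute_force_fps(p_exp: dict, p_scrambles: list[dict]) -> dict:
    """Literal double-loop FPS definition."""
    out = {}
    for g, pg in p_exp.items():
        per_scramble = [sum(ps[g2] <= pg for g2 in ps) for ps in p_scrambles]
        num = sorted(per_scramble)[(len(per_scramble) - 1) // 2]
        den = sum(p2 <= pg for p2 in p_exp.values())
        out[g] = num / den
    return out


def simple_map(cell_clones: dict) -> CellCloneMap:
    return CellCloneMap(assignments=dict(cell_clones))


class TestCellsForGroups:
    GROUPING = CloneGrouping(frozenset({"B1"}), frozenset({"B2"}))

    def test_cells_follow_their_clone(self):
        m = simple_map({"c1": "B1", "c2": "B1", "c3": "B1", "c4": "B2"})
        a, b = cells_for_groups(m, self.GROUPING)
        assert a == {"c1", "c2", "c3"} and b == {"c4"}

    def test_excluded_cells_in_neither_group(self):
        m = CellCloneMap(assignments={"c1": "B1", "c2": "B2"},
                         excluded_multimapped={"cx"})
        a, b = cells_for_groups(m, self.GROUPING)
        assert "cx" not in a | b

    def test_out_of_group_clone_ignored(self):
        m = simple_map({"c1": "B1", "c2": "B2", "c3": "B9"})
        a, b = cells_for_groups(m, self.GROUPING)
        assert "c3" not in a | b

    def test_empty_group_raises(self):
        m = simple_map({"c1": "B1", "c2": "B1"})
        with pytest.raises(ValueError, match="no mapped cells"):
            cells_for_groups(m, self.GROUPING)


class TestMannWhitney:
    def test_worked_enumeration_examples(self):
        # A={1,2} vs B={3,4}, B greater: only 1 of C(4,2)=6 arrangements as extreme
        r = mannwhitney_per_gene([[1], [2]], [[3], [4]], "b_greater")
        assert r["p"][0] == pytest.approx(1 / 6)
        # A={5,6,7} vs B={1,2,3}, A greater: 1 of C(6,3)=20
        r = mannwhitney_per_gene([[5], [6], [7]], [[1], [2], [3]], "a_greater")
        assert r["p"][0] == pytest.approx(1 / 20)

    def test_identical_groups_p_at_least_half(self):
        vals = [[1.0], [2.0], [3.0]]
        for d in ("a_greater", "b_greater"):
            assert mannwhitney_per_gene(vals, vals, d)["p"][0] >= 0.5

    def test_all_tied_gene_is_degenerate(self):
        r = mannwhitney_per_gene([[1.0], [1.0]], [[1.0], [1.0]], "a_greater")
        assert bool(r["degenerate"][0])
        assert r["p"][0] == 0.5

    @pytest.mark.parametrize("n_a,n_b", [(2, 2), (2, 5), (3, 3), (4, 6), (5, 5)])
    @pytest.mark.parametrize("direction", ["a_greater", "b_greater"])
    def test_matches_enumeration_oracle_tie_free(self, n_a, n_b, direction):
        rng = np.random.default_rng(n_a * 100 + n_b)
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = vals[:n_a], vals[n_a:]
            got = mannwhitney_per_gene(a[:, None], b[:, None], direction)["p"][0]
            assert got == pytest.approx(enumeration_pvalue(a, b, direction))

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            mannwhitney_per_gene([[1]], [[2], [3]], "a_greater")


class TestScrambleMap:
    def big_map(self, n=100):
        return simple_map({f"c{i:03d}": f"B{i % 7}" for i in range(n)})

    def test_label_multiset_preserved(self):
        m = self.big_map()
        s = scramble_map(m, seed=3)
        assert sorted(s.assignments.values()) == sorted(m.assignments.values())
        assert set(s.assignments) == set(m.assignments)

    def test_deterministic_under_seed(self):
        m = self.big_map()
        assert scramble_map(m, 5).assignments == scramble_map(m, 5).assignments

    def test_different_seeds_differ(self):
        m = self.big_map()
        assert scramble_map(m, 1).assignments != scramble_map(m, 2).assignments

    def test_clone_mode_preserves_cell_blocks(self):
        m = self.big_map()
        s = scramble_map(m, seed=4, mode="clone")
        blocks = {}
        for cell, clone in m.assignments.items():
            blocks.setdefault(clone, set()).add(cell)
        new_blocks = {}
        for cell, clone in s.assignments.items():
            new_blocks.setdefault(clone, set()).add(cell)
        assert sorted(map(frozenset, blocks.values())) == \
            sorted(map(frozenset, new_blocks.values()))

    def test_fewer_than_two_cells_raises(self):
        with pytest.raises(ValueError):
            scramble_map(simple_map({"c1": "B1"}), 0)

    def test_excluded_sets_pass_through(self):
        m = CellCloneMap(assignments={"c1": "B1", "c2": "B2"},
                         excluded_multimapped={"cx"}, unmapped_cells={"cy"})
        s = scramble_map(m, 0)
        assert s.excluded_multimapped == {"cx"} and s.unmapped_cells == {"cy"}


class TestComputeFps:
    def test_scrambles_identical_to_experiment_give_one(self):
        p = pd.Series({"g1": 0.01, "g2": 0.2, "g3": 0.9})
        fps = compute_fps(p, [p] * 5)
        assert (fps == 1.0).all()

    def test_worked_example_zero_fps(self):
        p_exp = pd.Series({"g1": 0.001, "g2": 0.5})
        scr = pd.Series({"g1": 0.4, "g2": 0.6})
        fps = compute_fps(p_exp, [scr] * 5)
        assert fps["g1"] == 0.0  # no scramble gene at or below 0.001; denominator 1
        assert fps["g2"] == pytest.approx(1 / 2)  # one scramble gene <= 0.5, two experimental

    def test_deterministic(self, rng):
        genes = [f"g{i}" for i in range(30)]
        p_exp = pd.Series(rng.random(30), index=genes)
        scr = [pd.Series(rng.random(30), index=genes) for _ in range(5)]
        pd.testing.assert_series_equal(compute_fps(p_exp, scr),
                                       compute_fps(p_exp, scr))

    def test_gene_set_mismatch_raises(self):
        p = pd.Series({"g1": 0.1})
        with pytest.raises(ValueError, match="gene set"):
            compute_fps(p, [pd.Series({"g2": 0.1})])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            genes = [f"g{i}" for i in range(n)]
            p_exp = pd.Series(np.round(rng.random(n), 3), index=genes)
            scrambles = [pd.Series(np.round(rng.random(n), 3), index=genes)
                         for _ in range(5)]
            expected = brute_force_fps(p_exp.to_dict(),
                                       [s.to_dict() for s in scrambles])
            got = compute_fps(p_exp, scrambles)
            for g in genes:
                assert got[g] == expected[g]


class TestCallSignificant:
    @pytest.mark.parametrize("p,fps,expected", [
        (0.04, 0.04, True),
        (0.05, 0.0, False),   # strict on p
        (0.01, 0.06, False),  # strict on fps
        (0.04, 0.05, False),
    ])
    def test_strict_dual_threshold(self, p, fps, expected):
        df = pd.DataFrame({"gene": ["g"], "p": [p], "fps": [fps]})
        assert call_significant(df)["significant"][0] == expected

    def test_sorted_by_p_with_stable_gene_ties(self):
        df = pd.DataFrame({"gene": ["gB", "gA", "gC"],
                           "p": [0.5, 0.01, 0.01],
                           "fps": [1.0, 0.0, 0.0]})
        out = call_significant(df)
        assert out["gene"].tolist() == ["gA", "gC", "gB"]


class TestCloneGroupDGEModel:
    def make_planted(self, seed=0, fold=4.0, n_cells=240, n_genes=60):
        """Two clones, half the cells each, genes 0/1 planted up in A/B."""
        import anndata as ad
        rng = np.random.default_rng(seed)
        cells = [f"cell{i:04d}" for i in range(n_cells)]
        clones = {c: ("B1" if i < n_cells // 2 else "B2")
                  for i, c in enumerate(cells)}
        mean = np.full((n_cells, n_genes), 5.0)
        in_a = np.array([clones[c] == "B1" for c in cells])
        mean[in_a, 0] *= fold
        mean[~in_a, 1] *= fold
        X = rng.poisson(mean)
        adata = ad.AnnData(X=X.astype(np.int64),
                           obs=pd.DataFrame(index=cells),
                           var=pd.DataFrame(index=[f"G{j}" for j in range(n_genes)]))
        from clonotrx.sc_preprocess import normalize_expression
        adata = normalize_expression(adata)
        return adata, simple_map(clones)

    def test_planted_genes_recovered_in_both_directions(self):
        adata, ccmap = self.make_planted()
        up_in_a = CloneGrouping(frozenset({"B1"}), frozenset({"B2"}),
                                direction="a_greater")
        res_a = CloneGroupDGE(adata, ccmap, up_in_a).fit(seed=0)
        res_b = CloneGroupDGE(adata, ccmap, up_in_a.flipped()).fit(seed=0)
        assert "G0" in res_a.significant_genes
        assert "G1" in res_b.significant_genes
        assert "G1" not in res_a.significant_genes

    def test_fit_is_deterministic_under_seed(self):
        adata, ccmap = self.make_planted()
        g = CloneGrouping(frozenset({"B1"}), frozenset({"B2"}))
        r1 = CloneGroupDGE(adata, ccmap, g).fit(seed=11)
        r2 = CloneGroupDGE(adata, ccmap, g).fit(seed=11)
        pd.testing.assert_frame_equal(r1.results, r2.results)

    def test_summary_reports_counts_and_thresholds(self):
        adata, ccmap = self.make_planted(n_cells=60, n_genes=10)
        g = CloneGrouping(frozenset({"B1"}), frozenset({"B2"}), label="B1 vs B2")
        s = CloneGroupDGE(adata, ccmap, g).fit(seed=0).summary()
        assert "B1 vs B2" in s and "n_a=30" in s and "FPS < 0.05" in s

    def test_missing_layer_raises(self):
        import anndata as ad
        adata = ad.AnnData(X=np.ones((4, 3)))
        with pytest.raises(ValueError, match="normalized"):
            CloneGroupDGE(adata, simple_map({"0": "B1", "1": "B2"}),
                          CloneGrouping(frozenset({"B1"}), frozenset({"B2"})))
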