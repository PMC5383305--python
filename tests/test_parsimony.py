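import numpy as np
import pytest

from conftest import random_matrix
from oracles import (
    all_rooted_topologies,
    brute_force_best_trees,
    brute_force_fitch,
    brute_force_min_max_steps,
    brute_force_unambiguous_changes,
)

from hadroclad.nexus import MISSING, CharacterMatrix
from hadroclad.parsimony import (
    SearchConfig,
    _rerootings,
    bootstrap_support,
    bremer_support,
    char_max_steps,
    char_min_steps,
    collapse_zero_length_branches,
    ensemble_indices,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    map_synapomorphies,
)
from hadroclad.trees import TreeError, read_newick, strict_consensus, write_newick

f = frozenset


def shape_newick(shape):
    if not isinstance(shape, tuple):
        return shape
    return "(" + shape_newick(shape[0]) + "," + shape_newick(shape[1]) + ")"


def shape_to_tree(shape):
    return read_newick(shape_newick(shape) + ";")


class TestFitchLength:
    def test_constant_character_is_free(self):
        m = CharacterMatrix(list("ABCD"), [[f("0")]] * 4)
        t = read_newick("((A,B),(C,D));")
        assert fitch_length(t, m) == (0, [0])

    def test_single_split_character(self):
        m = CharacterMatrix(list("ABCD"),
                            [[f("0")], [f("0")], [f("1")], [f("1")]])
        t = read_newick("((A,B),(C,D));")
        assert fitch_length(t, m)[0] == 1

    def test_missing_and_polymorphic_cells_never_force_changes(self):
        m = CharacterMatrix(list("ABCD"),
                            [[f("0")], [MISSING], [f("01")], [f("0")]])
        t = read_newick("((A,B),(C,D));")
        assert fitch_length(t, m)[0] == 0

    def test_polytomy_rejected(self):
        m = CharacterMatrix(list("ABC"), [[f("0")], [f("0")], [f("1")]])
        with pytest.raises(TreeError, match="binary"):
            fitch_length(read_newick("(A,B,C);"), m)

    def test_unknown_tip_named_in_error(self):
        m = CharacterMatrix(list("ABCD"), [[f("0")]] * 4)
        with pytest.raises(TreeError, match="Z"):
            fitch_length(read_newick("((A,B),(C,Z));"), m)

    def test_matches_brute_force_on_random_six_taxon_matrices(self, rng):
        for _ in range(8):
            m = random_matrix(rng, 6, 12, missing=0.2, polymorphic=0.1)
            shape = all_rooted_topologies(m.taxa)[int(rng.integers(105))]
            expected_total, expected_steps = brute_force_fitch(m, shape)
            total, steps = fitch_length(shape_to_tree(shape), m)
            assert total == expected_total
            assert steps.tolist() == expected_steps

    def test_invariant_to_rerooting(self, rng):
        m = random_matrix(rng, 6, 15, missing=0.1)
        base = all_rooted_topologies(m.taxa)[17]
        ref = fitch_length(shape_to_tree(base), m)[0]
        for rerooted in _rerootings(base):
            assert fitch_length(shape_to_tree(rerooted), m)[0] == ref


class TestCharStepBounds:
    def test_min_steps_examples(self):
        assert char_min_steps([f("0"), f("1"), f("2")]) == 2
        assert char_min_steps([MISSING, MISSING]) == 0
        # the polymorphic cell can side with either fixed state, but the
        # two fixed cells still differ: one step is unavoidable
        assert char_min_steps([f("01"), f("0"), f("1")]) == 1
        assert char_min_steps([f("01"), f("01")]) == 0
        assert char_min_steps([f("01"), f("2")]) == 1

    def test_max_steps_examples(self):
        col = [f("0"), f("0"), f("0"), f("1"), f("1"), f("2")]
        assert char_max_steps(col) == 3
        assert char_max_steps([f("0")] * 4) == 0
        assert char_max_steps([MISSING, f("1"), MISSING]) == 0

    def test_extrema_match_brute_force_over_all_topologies(self, rng):
        taxa = list("ABCDEF")
        for _ in range(6):
            col = [f(str(rng.integers(3))) if rng.random() > 0.2 else MISSING
                   for _ in taxa]
            lo, hi = brute_force_min_max_steps(col, taxa)
            assert char_min_steps(col) == lo
            assert char_max_steps(col) == hi

    def test_bounds_bracket_realized_steps_with_polymorphism(self, rng):
        for _ in range(6):
            m = random_matrix(rng, 6, 10, missing=0.2, polymorphic=0.15)
            shape = all_rooted_topologies(m.taxa)[int(rng.integers(105))]
            _, steps = fitch_length(shape_to_tree(shape), m)
            for c in range(m.n_char):
                col = m.column(c + 1)
                assert char_min_steps(col) <= steps[c] <= char_max_steps(col)


class TestEnsembleIndices:
    def test_hand_worked_matrix(self):
        # chars: A,B derived (no homoplasy); B,C derived (2 steps on this tree)
        m = CharacterMatrix(
            ["O", "A", "B", "C", "D"],
            [[f("0"), f("0")], [f("1"), f("0")], [f("1"), f("1")],
             [f("0"), f("1")], [f("0"), f("0")]],
        )
        t = read_newick("(O,(((A,B),C),D));")
        total, _ = fitch_length(t, m)
        assert total == 3
        idx = ensemble_indices(m, total)
        assert idx.ci_all == pytest.approx(2 / 3)
        assert idx.ri == pytest.approx((4 - 3) / (4 - 2))

    def test_zero_homoplasy_gives_ci_one(self):
        m = CharacterMatrix(list("ABCD"),
                            [[f("0")], [f("0")], [f("1")], [f("1")]])
        idx = ensemble_indices(m, 1)
        assert idx.ci_all == 1.0

    def test_ri_undefined_without_informative_variation(self):
        m = CharacterMatrix(list("ABCD"),
                            [[f("0")], [f("1")], [f("0")], [f("0")]])
        idx = ensemble_indices(m, 1)
        assert idx.ri is None


class TestSearch:
    def test_heuristic_equals_exhaustive_on_small_matrices(self, rng):
        for trial in range(10):
            n_taxa = int(rng.integers(5, 8))
            m = random_matrix(rng, n_taxa, 15, missing=0.15)
            cfg = SearchConfig(outgroup=m.taxa[0], replicates=3, hold=50,
                               seed=trial)
            heur = heuristic_search(m, cfg)
            exact = exhaustive_search(m, cfg)
            assert heur.length == exact.length
            heur_keys = {frozenset(t.clades(include_trivial=True))
                         for t in heur.mpts}
            exact_keys = {frozenset(t.clades(include_trivial=True))
                          for t in exact.mpts}
            assert heur_keys == exact_keys

    def test_single_binary_character_yields_all_trees_showing_split(self, rng):
        taxa = ["O", "A", "B", "C", "D"]
        m = CharacterMatrix(
            taxa, [[f("0")], [f("1")], [f("1")], [f("0")], [f("0")]])
        cfg = SearchConfig(outgroup="O", replicates=2, hold=200, seed=1,
                           collapse=True)
        res = exhaustive_search(m, cfg)
        assert res.length == 1
        for t in res.mpts:
            assert frozenset("AB") in t.clades() | {
                c for c in t.clades(include_trivial=True)}
        # on collapse, all compatible resolutions merge: the split is the
        # only surviving internal structure
        assert len(res.mpts) == 1
        assert res.mpts[0].clades() == {frozenset("AB")}

    def test_seed_determinism_bit_identical(self, rng):
        m = random_matrix(rng, 7, 20, missing=0.1)
        cfg = SearchConfig(outgroup=m.taxa[0], replicates=3, hold=30, seed=9)
        r1 = heuristic_search(m, cfg)
        r2 = heuristic_search(m, cfg)
        assert r1.length == r2.length
        assert [write_newick(t) for t in r1.mpts] == \
               [write_newick(t) for t in r2.mpts]

    def test_spr_and_nni_also_find_optimum_on_easy_matrix(self, rng):
        m = random_matrix(rng, 6, 25, missing=0.0)
        ref = exhaustive_search(
            m, SearchConfig(outgroup=m.taxa[0], replicates=1, seed=1)).length
        for swap in ("spr", "nni"):
            cfg = SearchConfig(outgroup=m.taxa[0], replicates=5, hold=20,
                               seed=2, swap=swap)
            assert heuristic_search(m, cfg).length == ref

    def test_too_few_taxa_rejected(self):
        m = CharacterMatrix(list("ABC"), [[f("0")], [f("0")], [f("1")]])
        with pytest.raises(TreeError):
            heuristic_search(m, SearchConfig(outgroup="A"))

    def test_outgroup_must_exist(self, rng):
        m = random_matrix(rng, 5, 5)
        with pytest.raises(TreeError, match="Zed"):
            heuristic_search(m, SearchConfig(outgroup="Zed"))

    def test_length_at_least_sum_of_minima(self, rng):
        for trial in range(5):
            m = random_matrix(rng, 6, 12, missing=0.2)
            cfg = SearchConfig(outgroup=m.taxa[0], replicates=2, hold=20,
                               seed=trial)
            res = heuristic_search(m, cfg)
            assert res.length >= res.min_steps.sum()


class TestHeuristicMatchesBruteForce:
    def test_full_brute_force_cross_check(self, rng):
        # independent scorer AND independent enumerator, tiny instance
        m = random_matrix(rng, 5, 8, missing=0.1)
        best, optimal = brute_force_best_trees(m, m.taxa[0])
        cfg = SearchConfig(outgroup=m.taxa[0], replicates=3, hold=50, seed=3,
                           collapse=False)
        res = heuristic_search(m, cfg)
        assert res.length == best
        expected = {
            frozenset(shape_to_tree(s).clades(include_trivial=True))
            for s in optimal
        }
        got = {frozenset(t.clades(include_trivial=True)) for t in res.mpts}
        assert got == expected


class TestBootstrap:
    def test_universal_clade_scores_100(self):
        # A,B identical across many characters: every replicate recovers them
        m = CharacterMatrix(
            ["O", "A", "B", "C", "D"],
            [[f("0")] * 10,
             [f("1")] * 10,
             [f("1")] * 10,
             [f("0")] * 5 + [f("1")] * 5,
             [f("0")] * 10],
        )
        cfg = SearchConfig(outgroup="O", replicates=2, hold=10, seed=1)
        table = bootstrap_support(m, cfg, 25)
        found = {clade for clade in table.entries
                 if table.entries[clade]["bootstrap"] == 100.0}
        assert frozenset("AB") in found

    def test_determinism_and_taxon_order_invariance(self, rng):
        m = random_matrix(rng, 6, 20, missing=0.1)
        cfg = SearchConfig(outgroup=m.taxa[0], replicates=2, hold=10, seed=5)
        t1 = bootstrap_support(m, cfg, 15)
        t2 = bootstrap_support(m, cfg, 15)
        assert t1.entries == t2.entries


class TestBremer:
    def test_clade_absent_from_some_mpt_decays_at_zero(self, rng):
        # two exactly conflicting characters: both resolutions are MPTs
        m = CharacterMatrix(
            ["O", "A", "B", "C"],
            [[f("0"), f("0")], [f("1"), f("1")], [f("1"), f("0")],
             [f("0"), f("1")]],
        )
        cfg = SearchConfig(outgroup="O", replicates=2, hold=20, seed=1,
                           collapse=False)
        res = exhaustive_search(m, cfg)
        table = bremer_support(m, res.mpts, cfg)
        assert all(v["bremer"] == 0 for v in table.entries.values()) or \
            not table.entries

    def test_matches_exhaustive_definition_on_small_matrices(self, rng):
        for trial in range(4):
            m = random_matrix(rng, 6, 15, missing=0.1)
            cfg = SearchConfig(outgroup=m.taxa[0], replicates=3, hold=40,
                               seed=trial)
            res = exhaustive_search(m, cfg)
            table = bremer_support(m, res.mpts, cfg)
            # oracle: per consensus clade, search all topologies directly
            cons = strict_consensus(res.mpts)
            for clade in cons.clades():
                if m.taxa[0] in clade:
                    continue
                best_without = None
                for shape in all_rooted_topologies(m.taxa):
                    t = shape_to_tree(shape)
                    if clade in t.clades(include_trivial=True):
                        continue
                    length = fitch_length(t, m)[0]
                    if best_without is None or length < best_without:
                        best_without = length
                assert table.entries[clade]["bremer"] == \
                    best_without - res.length


class TestSynapomorphies:
    def test_single_split_character_maps_to_subtending_branch(self):
        m = CharacterMatrix(
            ["O", "A", "B", "C"],
            [[f("0")], [f("1")], [f("1")], [f("0")]],
        )
        t = read_newick("(O,((A,B),C));")
        syn = map_synapomorphies(t, m)
        ab_node = t.find_clade({"A", "B"})
        assert syn[ab_node] == [(1, "1")]
        others = {node for node in syn if node is not ab_node}
        assert all(not syn[node] for node in others)

    def test_matches_brute_force_reconstruction_sets(self, rng):
        for trial in range(5):
            m = random_matrix(rng, 5, 8, missing=0.15)
            shape = all_rooted_topologies(m.taxa)[int(rng.integers(15))]
            expected = brute_force_unambiguous_changes(m, shape)
            t = shape_to_tree(shape)
            syn = map_synapomorphies(t, m)
            cmap = t.clade_map()
            got = {
                frozenset(cmap[node]): {(c, s) for c, s in changes}
                for node, changes in syn.items() if changes
            }
            assert got == expected


class TestCollapse:
    def test_unsupported_branch_collapses(self):
        m = CharacterMatrix(
            ["O", "A", "B", "C", "D"],
            [[f("0")], [f("1")], [f("1")], [f("0")], [f("0")]],
        )
        t = read_newick("(O,(((A,B),C),D));")
        collapsed = collapse_zero_length_branches(t, m)
        assert collapsed.clades() == {frozenset("AB")}
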