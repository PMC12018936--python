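import pytest

from paleocroc import io_formats as io
from paleocroc import parsimony as P
from paleocroc.io_formats import MISSING, CharacterMatrix

from _oracles import enumerate_char, enumerate_matrix_length
from conftest import random_matrix, random_tuple_tree


def single_char_matrix(states: dict[str, frozenset[int] | int], ordered: bool) -> CharacterMatrix:
    taxa = sorted(states)
    cells = []
    for t in taxa:
        s = states[t]
        cells.append([frozenset([s]) if isinstance(s, int) else frozenset(s)])
    return CharacterMatrix(taxa=taxa, cells=cells, ordered=[ordered])


class TestTreeLength:
    def test_uniform_tips_have_zero_length(self):
        m = single_char_matrix({"A": 1, "B": 1, "C": 1, "D": 1}, ordered=False)
        assert P.tree_length((("A", "B"), ("C", "D")), m) == 0

    @pytest.mark.parametrize("ordered,expected", [(False, 1), (True, 2)])
    def test_two_state_jump_costs(self, ordered, expected):
        m = single_char_matrix({"A": 0, "B": 0, "C": 2, "D": 2}, ordered=ordered)
        assert P.tree_length((("A", "B"), ("C", "D")), m) == expected

    def test_missing_tip_raises_naming_tip(self):
        m = single_char_matrix({"A": 0, "B": 1}, ordered=False)
        with pytest.raises(P.ParsimonyError, match="Zork"):
            P.tree_length(("A", ("B", "Zork")), m)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 8))
            m = random_matrix(rng, n_taxa=n, n_chars=int(rng.integers(2, 6)))
            tree = random_tuple_tree(rng, list(m.taxa))
            assert P.tree_length(tree, m) == enumerate_matrix_length(tree, m)

    def test_all_missing_character_adds_nothing(self, rng):
        m = random_matrix(rng, n_taxa=6, n_chars=4)
        tree = random_tuple_tree(rng, list(m.taxa))
        base = P.tree_length(tree, m)
        padded = CharacterMatrix(
            taxa=list(m.taxa),
            cells=[row + [MISSING] for row in m.cells],
            ordered=m.ordered + [False],
        )
        assert P.tree_length(tree, padded) == base

    def test_polytomy_scored_as_given(self):
        # hard polytomy (A,B,C) with states 0,1,2 needs 2 steps from any root state
        m = single_char_matrix({"A": 0, "B": 1, "C": 2, "D": 0}, ordered=False)
        t = io.read_newick("((A,B,C),D);")
        assert P.tree_length(t, m) == 2


class TestMprStates:
    def test_uniform_tips_reconstruct_uniform(self):
        m = single_char_matrix({"A": 2, "B": 2, "C": 2}, ordered=False)
        result = P.mpr_states((("A", "B"), "C"), m)
        assert all(s == frozenset([2]) for s in result.values())

    def test_three_one_split_forces_majority_root(self):
        m = single_char_matrix({"A": 0, "B": 1, "C": 1, "D": 1}, ordered=False)
        tree = (("A", "B"), ("C", "D"))
        result = P.mpr_states(tree, m)
        root = max(result)  # root is last in postorder
        assert result[root] == frozenset([1])

    def test_ordered_cherry_spans_the_cline(self):
        m = single_char_matrix({"A": 0, "B": 2}, ordered=True)
        result = P.mpr_states(("A", "B"), m)
        assert result[2] == frozenset([0, 1, 2])

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 8))
            m = random_matrix(rng, n_taxa=n, n_chars=1)
            tree = random_tuple_tree(rng, list(m.taxa))
            got = P.mpr_states(tree, m, char_index=0)
            tip_states = {t: m.cells[i][0] for i, t in enumerate(m.taxa)}
            _, expected = enumerate_char(
                tree, tip_states, max(m.n_states(0), 1), m.ordered[0]
            )
            assert got == expected

    def test_tip_sets_restricted_to_observed_ambiguity(self, rng):
        m = single_char_matrix(
            {"A": frozenset([0, 1]), "B": 1, "C": 1}, ordered=False
        )
        result = P.mpr_states((("A", "B"), "C"), m)
        # tip A (postorder index 0) can only keep MPR-compatible member 1
        assert result[0] == frozenset([1])


class TestConsensus:
    def test_identical_inputs_return_same_tree(self):
        t = io.read_newick("((A,B),(C,D));")
        sc = P.strict_consensus([t, t.clone(depth=1)])
        assert P.rooted_clades(sc) == P.rooted_clades(t)

    def test_conflicting_clade_collapses(self):
        a = io.read_newick("((A,B),(C,(D,E)));")
        b = io.read_newick("((A,B),((C,D),E));")
        sc = P.strict_consensus([a, b])
        assert P.rooted_clades(sc) == {
            frozenset("AB"), frozenset("CDE"), frozenset("ABCDE")
        }

    def test_clade_set_is_intersection(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(15):
            trees = [random_tuple_tree(rng, taxa) for _ in range(3)]
            expected = P.rooted_clades(trees[0])
            for t in trees[1:]:
                expected &= P.rooted_clades(t)
            sc = P.strict_consensus(trees)
            assert {c for c in P.rooted_clades(sc) if len(c) >= 2} == {
                c for c in expected if len(c) >= 2
            }

    def test_idempotent_and_order_invariant(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        trees = [random_tuple_tree(rng, taxa) for _ in range(3)]
        sc1 = P.strict_consensus(trees)
        sc2 = P.strict_consensus(trees[::-1])
        assert P.rooted_clades(sc1) == P.rooted_clades(sc2)
        assert P.rooted_clades(P.strict_consensus([sc1])) == P.rooted_clades(sc1)

    def test_taxon_mismatch_rejected(self):
        a = io.read_newick("((A,B),C);")
        b = io.read_newick("((A,B),D);")
        with pytest.raises(P.ParsimonyError):
            P.strict_consensus([a, b])


class TestReducedConsensus:
    def test_empty_prune_equals_strict(self, rng):
        taxa = [f"t{i}" for i in range(5)]
        trees = [random_tuple_tree(rng, taxa) for _ in range(2)]
        assert P.rooted_clades(P.reduced_consensus(trees, [])) == P.rooted_clades(
            P.strict_consensus(trees)
        )

    def test_pruning_the_rogue_restores_resolution(self):
        # rogue R attaches in two different places; backbone is identical
        a = io.read_newick("(((A,R),B),(C,D));")
        b = io.read_newick("((A,B),(C,(D,R)));")
        blurred = P.strict_consensus([a, b])
        cleaned = P.reduced_consensus([a, b], ["R"])
        n_taxa = 4
        assert len([c for c in P.rooted_clades(cleaned) if len(c) >= 2]) == n_taxa - 1
        assert len(P.rooted_clades(cleaned)) > len(
            {c - {"R"} for c in P.rooted_clades(blurred) if len(c - {"R"}) >= 2}
        )

    def test_resolution_never_below_restricted_strict(self, rng):
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(10):
            trees = [random_tuple_tree(rng, taxa) for _ in range(2)]
            plain = P.strict_consensus(trees)
            pruned = P.reduced_consensus(trees, ["t0"])
            restricted = {
                frozenset(c - {"t0"})
                for c in P.rooted_clades(plain)
                if len(c - {"t0"}) >= 2
            }
            assert len(P.rooted_clades(pruned)) >= len(restricted)

    def test_pruning_everything_rejected(self):
        t = io.read_newick("(A,B);")
        with pytest.raises(P.ParsimonyError):
            P.reduced_consensus([t], ["A", "B"])


class TestScaffold:
    def test_fossils_may_attach_inside_backbone_clades(self):
        con = P.ScaffoldConstraint(backbone=io.read_newick("(A,(B,C));"))
        assert P.satisfies_scaffold(io.read_newick("((A,x),((B,y),C));"), con)

    def test_moving_a_constrained_taxon_violates(self):
        con = P.ScaffoldConstraint(backbone=io.read_newick("(A,(B,C));"))
        assert not P.satisfies_scaffold(io.read_newick("((B,(A,x)),(C,y));"), con)

    def test_empty_backbone_always_satisfied(self):
        assert P.satisfies_scaffold(io.read_newick("((A,B),C);"), P.ScaffoldConstraint())
        assert P.satisfies_scaffold(io.read_newick("((A,B),C);"), None)


class TestHeuristicSearch:
    def test_four_taxa_matches_exhaustive(self, rng):
        m = random_matrix(rng, n_taxa=4, n_chars=6, p_missing=0.0, p_poly=0.0)
        topos = P.all_unrooted_topologies(m.taxa)
        assert len(topos) == 3
        best = min(P.tree_length(t, m) for t in topos)
        found = P.heuristic_search(m, config=P.SearchConfig(n_replicates=2, seed=5))
        assert P.tree_length(found[0], m) == best

    def test_seven_taxa_matches_exhaustive(self, rng):
        m = random_matrix(rng, n_taxa=7, n_chars=10)
        topos = P.all_unrooted_topologies(m.taxa)
        assert len(topos) == 945
        best = min(P.tree_length(t, m) for t in topos)
        found = P.heuristic_search(m, config=P.SearchConfig(n_replicates=3, seed=5))
        assert P.tree_length(found[0], m) == best

    def test_constrained_search_respects_scaffold(self, rng):
        m = random_matrix(rng, n_taxa=7, n_chars=10)
        backbone = io.read_newick("(t1,(t2,t3));")
        con = P.ScaffoldConstraint(backbone=backbone)
        found = P.heuristic_search(
            m, constraint=con, config=P.SearchConfig(n_replicates=3, seed=5)
        )
        assert found
        assert all(P.satisfies_scaffold(t, con) for t in found)

    def test_deterministic_given_seed(self, rng):
        m = random_matrix(rng, n_taxa=6, n_chars=8)
        cfg = P.SearchConfig(n_replicates=2, seed=11)
        a = P.heuristic_search(m, config=cfg)
        b = P.heuristic_search(m, config=cfg)
        newick = lambda trees: [
            t.as_string(schema="newick", suppress_rooting=True) for t in trees
        ]
        assert newick(a) == newick(b)

    def test_more_replicates_never_worse(self, rng):
        m = random_matrix(rng, n_taxa=7, n_chars=8)
        lengths = []
        for reps in (1, 3, 6):
            found = P.heuristic_search(
                m, config=P.SearchConfig(n_replicates=reps, seed=3)
            )
            lengths.append(P.tree_length(found[0], m))
        assert lengths[0] >= lengths[1] >= lengths[2]

    def test_outgroup_is_child_of_root(self, rng):
        m = random_matrix(rng, n_taxa=5, n_chars=6)
        found = P.heuristic_search(
            m, config=P.SearchConfig(n_replicates=1, seed=2, outgroup="t3")
        )
        for t in found:
            root_children = t.seed_node.child_nodes()
            tips = [c.taxon.label for c in root_children if c.is_leaf()]
            assert "t3" in tips
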