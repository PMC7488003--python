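"""MST-guided tree growth: initialization, clustering, tallying, recruiting."""

import numpy as np
import pytest

from conftest import random_instances
from lineagemst.edit_space import EditOperation, edit_distance
from lineagemst.growth import (
    assign_clusters,
    build_guide_mst,
    grow_step,
    initialize,
    reconstruct,
    select_origination_operation,
    tally_operations,
)


@pytest.fixture
def aa_state():
    return initialize("AA", ["CA", "CC", "CG"], np.random.default_rng(0))


class TestInitialize:
    def test_root_only_tree_and_standby_pool(self, aa_state):
        assert aa_state.tree.size == 1
        assert aa_state.tree.root.sequence == "AA"
        assert not aa_state.tree.root.observed
        assert {n.sequence for n in aa_state.standby.values()} == {"CA", "CC", "CG"}

    def test_duplicate_observed_collapse_with_multiplicity(self):
        state = initialize("AA", ["CA", "CA"])
        assert len(state.standby) == 1
        (node,) = state.standby.values()
        assert node.multiplicity == 2

    def test_observed_root_marks_root(self):
        state = initialize("AA", ["AA", "CA"])
        assert state.tree.root.observed
        assert state.tree.root.multiplicity == 1
        assert {n.sequence for n in state.standby.values()} == {"CA"}

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            initialize("AA", [])


class TestGuideMst:
    def test_star_example_hangs_off_nearest_standby(self, aa_state):
        edges = {
            (aa_state.sequence_of(u), aa_state.sequence_of(v), w)
            for u, v, w in build_guide_mst(aa_state)
        }
        assert edges == {("AA", "CA", 1), ("CA", "CC", 1), ("CA", "CG", 1)}

    def test_single_standby_connects_to_nearest_tree_node(self):
        state = initialize("AA", ["CC"])
        ((u, v, w),) = build_guide_mst(state)
        assert (u, v, w) == (0, 1, 2)

    def test_total_crossing_weight_is_minimal(self):
        # exhaustive check over all 16 spanning trees of the 4-node graph
        state = initialize("AA", ["CA", "CC", "CG"])
        mst_weight = sum(w for _u, _v, w in build_guide_mst(state))
        seqs = ["AA", "CA", "CC", "CG"]
        import itertools

        best = None
        nodes = range(4)
        for edges in itertools.combinations(itertools.combinations(nodes, 2), 3):
            parents = list(nodes)

            def find(x):
                while parents[x] != x:
                    x = parents[x]
                return x

            ok = True
            for u, v in edges:
                ru, rv = find(u), find(v)
                if ru == rv:
                    ok = False
                    break
                parents[ru] = rv
            if ok:
                w = sum(edit_distance(seqs[u], seqs[v]) for u, v in edges)
                best = w if best is None else min(best, w)
        assert mst_weight == best


class TestClustersAndTallies:
    def test_star_example_single_cluster_from_root(self, aa_state):
        clusters = assign_clusters(build_guide_mst(aa_state), aa_state)
        assert len(clusters) == 1
        assert clusters[0].origination == aa_state.tree.root_id
        assert set(clusters[0].members) == set(aa_state.standby)

    def test_two_separated_standby_form_two_clusters(self):
        state = initialize("AAAAAA", ["CAAAAA", "AAAAAG"])
        clusters = assign_clusters(build_guide_mst(state), state)
        assert len(clusters) == 2
        assert all(len(c.members) == 1 for c in clusters)

    def test_star_example_tally_counts(self, aa_state):
        clusters = assign_clusters(build_guide_mst(aa_state), aa_state)
        tallies = tally_operations(clusters, aa_state)
        by_op = {str(op): count for (_orig, op), count in tallies.items()}
        assert by_op == {"sub:1:C": 3, "sub:2:C": 1, "sub:2:G": 1}

    def test_selection_takes_unique_maximum(self, aa_state):
        clusters = assign_clusters(build_guide_mst(aa_state), aa_state)
        tallies = tally_operations(clusters, aa_state)
        orig, op = select_origination_operation(tallies, aa_state.rng)
        assert orig == aa_state.tree.root_id
        assert str(op) == "sub:1:C"

    def test_tie_break_is_seed_reproducible(self):
        tallies = {
            (0, EditOperation("sub", 1, "C")): 2,
            (0, EditOperation("sub", 2, "G")): 2,
        }
        picks = {
            select_origination_operation(dict(tallies), np.random.default_rng(5))
            for _ in range(10)
        }
        assert len(picks) == 1

    def test_grow_step_recruits_matching_standby(self, aa_state):
        clusters = assign_clusters(build_guide_mst(aa_state), aa_state)
        selection = select_origination_operation(
            tally_operations(clusters, aa_state), aa_state.rng
        )
        grow_step(aa_state, selection)
        assert aa_state.tree.size == 2
        recruited = aa_state.tree.node(aa_state.tree.id_of_sequence("CA"))
        assert recruited.observed
        assert "CA" not in {n.sequence for n in aa_state.standby.values()}


class TestReconstruct:
    def test_star_example_reaches_optimal_four_nodes(self):
        tree = reconstruct("AA", ["CA", "CC", "CG"], seed=0)
        tree.validate()
        assert tree.size == 4
        edges = {
            (tree.node(p).sequence, tree.node(c).sequence) for p, c, _ in tree.edges()
        }
        assert edges == {("AA", "CA"), ("CA", "CC"), ("CA", "CG")}

    @pytest.mark.parametrize("obs", ["GGGG", "ACGTACGT", "A"])
    def test_single_observed_gives_minimal_chain(self, obs):
        root = "ACGT"
        tree = reconstruct(root, [obs], seed=0)
        tree.validate()
        assert tree.size == edit_distance(root, obs) + 1

    def test_observed_equal_to_root_gives_singleton(self):
        tree = reconstruct("ACGT", ["ACGT"], seed=0)
        assert tree.size == 1
        assert tree.root.observed

    def test_identical_seed_reproduces_identical_tree(self):
        inst = random_instances(1, np.random.default_rng(3))[0]
        edge_sets = []
        for _ in range(2):
            t = reconstruct(inst.root, inst.observed, seed=11)
            edge_sets.append(
                {(t.node(p).sequence, t.node(c).sequence) for p, c, _ in t.edges()}
            )
        assert edge_sets[0] == edge_sets[1]

    def test_random_instances_satisfy_all_tree_invariants(self):
        for inst in random_instances(12):
            tree = reconstruct(inst.root, inst.observed, seed=0)
            tree.validate()
            observed_seqs = {
                n.sequence for n in tree.nodes() if n.observed
            }
            assert observed_seqs == set(inst.observed) | (
                {inst.root} if inst.root in inst.observed else set()
            )

    def test_multiplicities_match_input_duplicates(self):
        tree = reconstruct("AA", ["CA", "CA", "CC"], seed=0)
        node = tree.node(tree.id_of_sequence("CA"))
        assert node.multiplicity == 2

    def test_never_worse_than_independent_paths(self):
        """Tree size bounded by the naive union of root-to-observed chains."""
        for inst in random_instances(10, np.random.default_rng(9)):
            tree = reconstruct(inst.root, inst.observed, seed=0)
            naive = 1 + sum(edit_distance(inst.root, o) for o in set(inst.observed))
            assert tree.size <= naive
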