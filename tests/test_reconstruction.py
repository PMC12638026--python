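"""Joint-ML ancestral states, insertion-order enforcement, deletion blocks."""

import math

import numpy as np
import pytest

from spacerorient.alignment import build_msaa, build_psio
from spacerorient.likelihood import BDMParams, reconstruction_log_likelihood
from spacerorient.reconstruction import (
    GainLossModel,
    enforce_psio,
    extract_deletion_blocks,
    find_contradictions,
    guide_reconstruction,
    index_tree,
    joint_ml_column,
    _younger_columns,
)
from spacerorient.trees import estimate_tree, read_newick, sample_coalescent_tree
from spacerorient.simulation import SimConfig, simulate_group

from .conftest import make_group
from .oracles import brute_force_joint_ml, best_psio_respecting_assignment


MODEL = GainLossModel(gain_rate=0.2, loss_rate=0.7)  # generic rates for DP checks


def states_of(tree, assignment):
    return {
        nd.taxon.label if nd.is_leaf() else nd.reconstruction_index: s
        for nd, s in (
            (nd, assignment[nd.reconstruction_index])
            for nd in tree.preorder_node_iter()
        )
    }


class TestJointMLColumn:
    def test_all_absent_leaves_give_all_absent_ancestors(self, three_leaf_tree):
        index_tree(three_leaf_tree)
        leaf_states = {"A": 0, "B": 0, "C": 0}
        assignment, ll = joint_ml_column(three_leaf_tree, leaf_states, MODEL)
        assert all(s == 0 for s in assignment.values())
        # log-likelihood = log P(root=0) + sum of log P00(t) terms
        expected = math.log(1 - MODEL.root_prior_present)
        for nd in three_leaf_tree.preorder_node_iter():
            if nd.parent_node is not None:
                expected += MODEL.log_transition(nd.edge.length)[0, 0]
        assert ll == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("leaves", [(1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)])
    def test_star_tree_matches_exhaustive_enumeration(self, leaves):
        tree = read_newick("(A:0.8,B:1.2,C:0.5);")
        index_tree(tree)
        leaf_states = dict(zip("ABC", leaves))
        assignment, ll = joint_ml_column(tree, leaf_states, MODEL)
        _, best_ll = brute_force_joint_ml(tree, leaf_states, MODEL)
        assert ll == pytest.approx(best_ll, abs=1e-12)

    def test_nested_tree_matches_enumeration_under_many_patterns(self):
        tree = read_newick("((A:0.4,B:0.9):0.3,(C:0.2,D:0.6):0.7);")
        index_tree(tree)
        for bits in range(16):
            leaf_states = {
                lab: (bits >> i) & 1 for i, lab in enumerate("ABCD")
            }
            _, ll = joint_ml_column(tree, leaf_states, MODEL)
            _, best_ll = brute_force_joint_ml(tree, leaf_states, MODEL)
            assert ll == pytest.approx(best_ll, abs=1e-12)

    def test_fixed_root_forces_presence_and_lowers_likelihood(self, three_leaf_tree):
        index_tree(three_leaf_tree)
        leaf_states = {"A": 0, "B": 0, "C": 0}
        root_idx = three_leaf_tree.seed_node.reconstruction_index
        free, ll_free = joint_ml_column(three_leaf_tree, leaf_states, MODEL)
        fixed, ll_fixed = joint_ml_column(
            three_leaf_tree, leaf_states, MODEL, frozenset({root_idx})
        )
        assert fixed[root_idx] == 1
        assert ll_fixed <= ll_free

    def test_nonfinite_branch_length_rejected(self):
        tree = read_newick("(A:1.0,B:nan);")
        index_tree(tree)
        with pytest.raises(ValueError, match="finite"):
            joint_ml_column(tree, {"A": 0, "B": 1}, MODEL)


class TestExtractDeletionBlocks:
    @pytest.mark.parametrize(
        "parent,child,expected",
        [
            ([1, 1, 1, 1, 1], [1, 0, 0, 0, 1], [[1, 2, 3]]),
            ([1, 0, 1, 1, 1], [1, 0, 0, 0, 1], [[2, 3]]),  # absent col joins run
            ([1, 1, 1, 1], [0, 1, 1, 0], [[0], [3]]),
            ([1, 1, 1], [1, 1, 1], []),
            ([0, 0, 0], [0, 0, 0], []),
        ],
    )
    def test_block_grouping(self, parent, child, expected):
        blocks = extract_deletion_blocks(np.array(parent), np.array(child))
        assert blocks == expected


class TestGuideReconstruction:
    def test_identical_arrays_yield_no_events(self, identical_group, two_leaf_tree):
        msaa = build_msaa(identical_group, build_psio(identical_group))
        recon = guide_reconstruction(msaa, two_leaf_tree, GainLossModel())
        assert recon.states.all()
        assert recon.total_insertions == 0
        assert recon.total_deleted_spacers == 0

    def test_nested_arrays_event_total_matches_per_column_optimum(self):
        group = make_group("g", [("A", [1, 2, 3]), ("B", [2, 3]), ("C", [3])])
        msaa = build_msaa(group, build_psio(group))
        labels, d = __import__("spacerorient").distance_matrix(group, BDMParams())
        tree = estimate_tree(labels, d, method="upgma")
        index_tree(tree)
        model = GainLossModel()
        recon = guide_reconstruction(msaa, tree, model)
        row_of = {rid: i for i, rid in enumerate(msaa.row_ids)}
        expected_ll = 0.0
        for j in range(msaa.n_columns):
            leaf_states = {
                nd.taxon.label: int(msaa.presence[row_of[nd.taxon.label], j])
                for nd in tree.leaf_node_iter()
            }
            _, best_ll = brute_force_joint_ml(tree, leaf_states, model)
            expected_ll += best_ll
        assert recon.guide_log_likelihood == pytest.approx(expected_ll, abs=1e-9)

    def test_single_column_equals_joint_ml(self, two_leaf_tree):
        group = make_group("g", [("A", [7]), ("B", [7])])
        msaa = build_msaa(group, build_psio(group))
        model = GainLossModel()
        recon = guide_reconstruction(msaa, two_leaf_tree, model)
        assignment, ll = joint_ml_column(
            two_leaf_tree, {"A": 1, "B": 1}, model
        )
        assert recon.guide_log_likelihood == pytest.approx(ll)
        for idx, s in assignment.items():
            assert recon.states[idx, 0] == s

    def test_missing_leaf_rows_rejected(self, three_leaf_tree):
        group = make_group("g", [("A", [1]), ("B", [1])])
        msaa = build_msaa(group, build_psio(group))
        with pytest.raises(ValueError, match=r"\['C'\]"):
            guide_reconstruction(msaa, three_leaf_tree, GainLossModel())


class TestEnforcePsio:
    def _pipeline(self, group, newick, model=None):
        model = model or GainLossModel()
        psio = build_psio(group)
        msaa = build_msaa(group, psio)
        tree = read_newick(newick)
        guide = guide_reconstruction(msaa, tree, model)
        return psio, msaa, guide, model

    def test_consistent_guide_is_fixpoint(self, identical_group):
        psio, msaa, guide, model = self._pipeline(identical_group, "(A:1.0,B:1.0);")
        enforced = enforce_psio(guide, psio, msaa, model)
        assert enforced.fixed == set()
        assert enforced.n_enforcement_sweeps == 0
        assert np.array_equal(enforced.states, guide.states)

    def test_no_contradiction_when_only_younger_spacer_missing(self):
        # leaf A=[1,2], leaf B=[2]; PSIO 2 -> 1 (2 older).  An insertion of
        # the younger spacer 1 below a node lacking 2's juniors is legal.
        group = make_group("g", [("A", [1, 2]), ("B", [2])])
        psio, msaa, guide, model = self._pipeline(group, "(A:1.0,B:1.0);")
        enforced = enforce_psio(guide, psio, msaa, model)
        assert enforced.fixed == set()

    def test_old_spacer_insertion_below_younger_is_fixed_rootward(self):
        # A=[1,3], B=[1]: the PSIO makes 3 older than 1.  The guide gains 3
        # on the branch into A, but 1 is already present at A's parent, so
        # the insertion of the older spacer contradicts the order; the fix
        # forces 3 present at the root, turning the event into a deletion
        # on the branch into B.
        group = make_group("g", [("A", [1, 3]), ("B", [1])])
        psio, msaa, guide, model = self._pipeline(group, "(A:0.5,B:0.5);")
        col3 = msaa.column_order.index(3)
        root_idx = guide.tree.seed_node.reconstruction_index
        assert guide.states[root_idx, col3] == 0  # guide violates the order
        enforced = enforce_psio(guide, psio, msaa, model)
        assert (root_idx, col3) in enforced.fixed
        assert enforced.states[root_idx, col3] == 1
        assert enforced.n_enforcement_sweeps >= 1
        # in the deletion-balanced scoring regime (event means <= 1) the
        # enforced reconstruction attains the exhaustive constrained optimum
        params = BDMParams(theta=1.0, rho=1.0, alpha=2.0)
        best_ll, best_states = best_psio_respecting_assignment(
            enforced.tree, msaa, psio, params
        )
        assert best_states[root_idx, col3] == 1
        assert reconstruction_log_likelihood(enforced, params) == pytest.approx(
            best_ll, abs=1e-9
        )

    def test_enforced_output_has_zero_contradictions_on_simulations(self):
        for seed in range(6):
            sim = simulate_group(SimConfig(n_groups=1, rng_seed=seed))
            psio = build_psio(sim.group)
            msaa = build_msaa(sim.group, psio)
            model = GainLossModel()
            guide = guide_reconstruction(msaa, sim.tree, model)
            enforced = enforce_psio(guide, psio, msaa, model)
            younger = _younger_columns(psio, msaa)
            assert find_contradictions(enforced, younger) == set()
            assert len(enforced.fixed) >= 0
            assert enforced.n_enforcement_sweeps <= (
                enforced.states.shape[0] * enforced.states.shape[1]
            )

    def test_fixed_pairs_grow_monotonically(self):
        group = make_group(
            "g", [("A", [1, 5, 6]), ("B", [2, 5, 6]), ("C", [3, 4, 5, 6])]
        )
        psio = build_psio(group)
        msaa = build_msaa(group, psio)
        tree = read_newick("((A:0.5,B:0.5):0.5,C:1.0);")
        model = GainLossModel(gain_rate=0.3, loss_rate=0.3)
        guide = guide_reconstruction(msaa, tree, model)
        enforced = enforce_psio(guide, psio, msaa, model)
        assert all(s == 1 for (n, c) in enforced.fixed
                   for s in [enforced.states[n, c]])

    def test_event_table_and_annotated_newick_exports(self):
        group = make_group("g", [("A", [1, 2, 3]), ("B", [3])])
        psio, msaa, guide, model = self._pipeline(group, "(A:1.0,B:1.0);")
        enforced = enforce_psio(guide, psio, msaa, model)
        table = enforced.event_table()
        assert table.splitlines()[0].startswith("branch_child\tevent_type")
        assert "insertion" in table or "deletion_block" in table
        assert "ins=" in enforced.annotated_newick()
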