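"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or closed
form, sharing no logic with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from spacerorient.alignment import MSAA, PSIO
from spacerorient.likelihood import BDMParams, reconstruction_log_likelihood
from spacerorient.reconstruction import (
    BranchEvents,
    GainLossModel,
    Reconstruction,
    compute_events,
    find_contradictions,
    index_tree,
)


def column_likelihood(tree, assignment: dict[int, int], leaf_states, model: GainLossModel) -> float:
    """Joint log-probability of one full (root + internal + leaf) assignment."""
    ll = 0.0
    for nd in tree.preorder_node_iter():
        i = nd.reconstruction_index
        state = leaf_states[nd.taxon.label] if nd.is_leaf() else assignment[i]
        if nd.parent_node is None:
            prior = model.root_prior_present
            ll += math.log(prior if state else 1.0 - prior)
        else:
            p = nd.parent_node.reconstruction_index
            pstate = (
                leaf_states[nd.parent_node.taxon.label]
                if nd.parent_node.is_leaf() else assignment[p]
            )
            logP = model.log_transition(float(nd.edge.length))
            ll += logP[pstate, state]
    return ll


def brute_force_joint_ml(tree, leaf_states, model, fixed_nodes=frozenset()):
    """Best internal assignment for one column by exhaustive enumeration."""
    internal = [nd.reconstruction_index for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best_ll, best_assign = -math.inf, None
    for combo in itertools.product((0, 1), repeat=len(internal)):
        assignment = dict(zip(internal, combo))
        if any(assignment.get(i, 1) != 1 for i in fixed_nodes):
            continue
        ll = column_likelihood(tree, assignment, leaf_states, model)
        if ll > best_ll:
            best_ll, best_assign = ll, assignment
    return best_assign, best_ll


def _states_matrix(tree, msaa: MSAA, internal_combo, internal_idx):
    n_nodes = sum(1 for _ in tree.preorder_node_iter())
    states = np.zeros((n_nodes, msaa.n_columns), dtype=np.int8)
    row_of = {rid: i for i, rid in enumerate(msaa.row_ids)}
    for nd in tree.preorder_node_iter():
        i = nd.reconstruction_index
        if nd.is_leaf():
            states[i] = msaa.presence[row_of[nd.taxon.label]]
    for (i, j), s in zip(internal_idx, internal_combo):
        states[i, j] = s
    return states


def best_psio_respecting_assignment(
    tree, msaa: MSAA, psio: PSIO, params: BDMParams
) -> tuple[float, np.ndarray | None]:
    """Maximum BDM log-likelihood over ALL internal assignments that are valid
    polarized-insertion histories: no insertion-order contradiction, and each
    spacer originates exactly once (root presence or a single insertion
    branch — under polarized acquisition every insertion mints a fresh
    spacer, so convergent re-gains of one column are impossible).
    Exponential in (#internal nodes x #columns); callers keep fixtures tiny."""
    parent_index, branch_length, node_name = index_tree(tree)
    internal = [
        nd.reconstruction_index for nd in tree.preorder_node_iter() if not nd.is_leaf()
    ]
    cells = [(i, j) for i in internal for j in range(msaa.n_columns)]
    col = msaa.column_index()
    younger_cols = {
        col[s]: np.array(sorted(col[y] for y in psio.older_than(s)), dtype=int)
        for s in msaa.column_order
    }
    best_ll, best_states = -math.inf, None
    for combo in itertools.product((0, 1), repeat=len(cells)):
        states = _states_matrix(tree, msaa, combo, cells)
        events = compute_events(tree, states, parent_index)
        recon = Reconstruction(
            tree=tree, column_order=list(msaa.column_order), states=states,
            fixed=set(), events=events, guide_log_likelihood=0.0,
            col_log_likelihood=np.zeros(msaa.n_columns),
            parent_index=parent_index, branch_length=branch_length,
            node_name=node_name,
        )
        if find_contradictions(recon, younger_cols):
            continue
        root_idx = tree.seed_node.reconstruction_index
        origins = states[root_idx].astype(int).copy()
        for ev in events.values():
            for c in ev.insertions:
                origins[c] += 1
        if (origins != 1).any():
            continue
        ll = reconstruction_log_likelihood(recon, params)
        if ll > best_ll:
            best_ll, best_states = ll, states
    return best_ll, best_states
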