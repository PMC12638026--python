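"""Ancestral presence/absence reconstruction with insertion-order enforcement.

Reconstruction proceeds in two steps.

1. *Guide reconstruction.*  Each MSAA column (one unique spacer) is treated
   as an independent two-state character evolving on the rooted tree under a
   continuous-time gain/loss chain.  The jointly most likely assignment of
   internal states is found exactly by the Pupko et al. dynamic program
   (max-product over the tree).  Because columns are independent, nothing at
   this stage stops a spacer from being "inserted" below a younger spacer —
   the guide need not respect the partial spacer insertion order (PSIO).

2. *PSIO enforcement.*  A contradiction is an insertion event of spacer x on
   a branch u -> v while some spacer y with x older than y (PSIO) is present
   at u: x would have had to exist before y did.  Every contradicting spacer
   is fixed to be present at the offending parent node, the affected columns
   are recomputed under those hard constraints, and the scan repeats until
   no contradictions remain.  Each sweep only adds (node, column) fixes, and
   a fixed insertion can only move root-ward, so termination is guaranteed —
   in the worst case contradicting spacers are acquired at the root.

Branch events are read off the final states: an insertion where the child
has a spacer the parent lacks, and deletions grouped into maximal blocks
that are contiguous in the *parent's* realized array (columns absent at the
parent cannot break a block, because they were not there to separate the
deleted spacers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .alignment import MSAA, PSIO


@dataclass
class GainLossModel:
    """Two-state (absent/present) continuous-time chain for the guide step.

    A small gain rate biases against convergent gains of the same spacer,
    matching the polarized model's premise that each unique spacer is
    acquired once.  The root prior defaults to the stationary distribution.
    """

    gain_rate: float = 1e-3
    loss_rate: float = 1.0
    root_prior_present: float | None = None

    def __post_init__(self) -> None:
        if self.gain_rate <= 0 or self.loss_rate <= 0:
            raise ValueError("rates must be positive")
        if self.root_prior_present is None:
            self.root_prior_present = self.gain_rate / (self.gain_rate + self.loss_rate)
        if not 0.0 <= self.root_prior_present <= 1.0:
            raise ValueError("root prior must be a probability")

    def log_transition(self, t: float) -> np.ndarray:
        """2x2 matrix of log P(child state | parent state) over time t."""
        if not math.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        r = self.gain_rate + self.loss_rate
        decay = math.exp(-r * t)
        p01 = (self.gain_rate / r) * (1.0 - decay)
        p10 = (self.loss_rate / r) * (1.0 - decay)
        with np.errstate(divide="ignore"):
            return np.log(np.array([[1.0 - p01, p01], [p10, 1.0 - p10]]))

    def log_root_prior(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(np.array([1.0 - self.root_prior_present, self.root_prior_present]))


@dataclass
class BranchEvents:
    insertions: list[int] = field(default_factory=list)  # column indices
    deletion_blocks: list[list[int]] = field(default_factory=list)

    @property
    def n_deleted_spacers(self) -> int:
        return sum(len(b) for b in self.deletion_blocks)


@dataclass
class Reconstruction:
    """Per-node presence states plus per-branch events on a rooted tree."""

    tree: dendropy.Tree
    column_order: list[int]
    states: np.ndarray  # (n_nodes, n_columns) int8, row index = node index
    fixed: set[tuple[int, int]]  # (node index, column index) forced present
    events: dict[int, BranchEvents]  # keyed by child node index
    guide_log_likelihood: float
    col_log_likelihood: np.ndarray
    parent_index: dict[int, int]
    branch_length: dict[int, float]
    node_name: dict[int, str]
    n_enforcement_sweeps: int = 0

    @property
    def total_deleted_spacers(self) -> int:
        return sum(ev.n_deleted_spacers for ev in self.events.values())

    @property
    def total_insertions(self) -> int:
        return sum(len(ev.insertions) for ev in self.events.values())

    def event_table(self) -> str:
        """Per-branch event TSV (branch, event_type, columns, block_length)."""
        rows = ["branch_child\tevent_type\tcolumns\tblock_length"]
        for child_idx, ev in sorted(self.events.items()):
            name = self.node_name[child_idx]
            for col in ev.insertions:
                rows.append(f"{name}\tinsertion\t{self.column_order[col]}\t1")
            for block in ev.deletion_blocks:
                cols = ",".join(str(self.column_order[c]) for c in block)
                rows.append(f"{name}\tdeletion_block\t{cols}\t{len(block)}")
        return "\n".join(rows) + "\n"

    def annotated_newick(self) -> str:
        """Newick with per-branch event counts as node comments."""
        for nd in self.tree.preorder_node_iter():
            idx = nd.reconstruction_index
            if idx in self.events:
                ev = self.events[idx]
                nd.annotations.drop()
                nd.annotations.add_new("ins", len(ev.insertions))
                nd.annotations.add_new("del_blocks", len(ev.deletion_blocks))
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, suppress_annotations=False
        ).strip()


def index_tree(tree: dendropy.Tree) -> tuple[dict[int, int], dict[int, float], dict[int, str]]:
    """Assign stable preorder indices; return (parent map, branch lengths, names)."""
    parent_index: dict[int, int] = {}
    branch_length: dict[int, float] = {}
    node_name: dict[int, str] = {}
    for i, nd in enumerate(tree.preorder_node_iter()):
        nd.reconstruction_index = i
        node_name[i] = nd.taxon.label if nd.taxon is not None else f"node{i}"
        if nd.parent_node is not None:
            parent_index[i] = nd.parent_node.reconstruction_index
            if nd.edge.length is None:
                raise ValueError(f"branch into {node_name[i]} has no length")
            branch_length[i] = float(nd.edge.length)
    return parent_index, branch_length, node_name


def joint_ml_column(
    tree: dendropy.Tree,
    leaf_states: dict[str, int],
    model: GainLossModel,
    fixed_nodes: frozenset[int] = frozenset(),
) -> tuple[dict[int, int], float]:
    """Jointly most likely ancestral assignment for one presence/absence column.

    Exact max-product dynamic program (Pupko et al.): for every node and every
    possible parent state, record the best state of the node's subtree; the
    root maximizes prior times subtree messages.  ``fixed_nodes`` (by node
    index) are hard-constrained to state 1.  Ties prefer absence (state 0),
    which implies fewer events.  Returns (node index -> state, log-likelihood).
    """
    best: dict[int, np.ndarray] = {}
    choice: dict[int, np.ndarray] = {}
    post = list(tree.postorder_node_iter())
    for nd in post:
        i = nd.reconstruction_index
        if nd.is_leaf():
            allowed = (leaf_states[nd.taxon.label],)
        elif i in fixed_nodes:
            allowed = (1,)
        else:
            allowed = (0, 1)
        if nd.parent_node is None:
            logprior = model.log_root_prior()
            best_ll, best_x = -math.inf, 0
            for x in allowed:
                ll = logprior[x] + sum(best[c.reconstruction_index][x] for c in nd.child_nodes())
                if ll > best_ll:
                    best_ll, best_x = ll, x
            root_state, root_ll = best_x, best_ll
        else:
            logP = model.log_transition(float(nd.edge.length))
            b = np.full(2, -math.inf)
            ch = np.zeros(2, dtype=np.int8)
            for s in (0, 1):
                for x in allowed:
                    ll = logP[s, x] + sum(
                        best[c.reconstruction_index][x] for c in nd.child_nodes()
                    )
                    if ll > b[s]:
                        b[s], ch[s] = ll, x
            best[i], choice[i] = b, ch
    states: dict[int, int] = {}
    for nd in tree.preorder_node_iter():
        i = nd.reconstruction_index
        if nd.parent_node is None:
            states[i] = root_state
        else:
            states[i] = int(choice[i][states[nd.parent_node.reconstruction_index]])
    return states, float(root_ll)


def extract_deletion_blocks(
    parent_state: np.ndarray, child_state: np.ndarray
) -> list[list[int]]:
    """Group deletions (parent 1 -> child 0) into maximal blocks contiguous in
    the parent's realized array; columns absent at the parent do not break a
    block."""
    blocks: list[list[int]] = []
    current: list[int] = []
    for j in range(len(parent_state)):
        if not parent_state[j]:
            continue
        if child_state[j]:
            if current:
                blocks.append(current)
                current = []
        else:
            current.append(j)
    if current:
        blocks.append(current)
    return blocks


def compute_events(
    tree: dendropy.Tree, states: np.ndarray, parent_index: dict[int, int]
) -> dict[int, BranchEvents]:
    events: dict[int, BranchEvents] = {}
    for child_idx, par_idx in parent_index.items():
        parent_state, child_state = states[par_idx], states[child_idx]
        ins = [int(j) for j in np.nonzero((parent_state == 0) & (child_state == 1))[0]]
        events[child_idx] = BranchEvents(
            insertions=ins,
            deletion_blocks=extract_deletion_blocks(parent_state, child_state),
        )
    return events


def guide_reconstruction(
    msaa: MSAA, tree: dendropy.Tree, model: GainLossModel
) -> Reconstruction:
    """Column-independent joint-ML reconstruction (may violate the PSIO)."""
    parent_index, branch_length, node_name = index_tree(tree)
    leaves = {nd.taxon.label for nd in tree.leaf_node_iter()}
    missing = sorted(leaves - set(msaa.row_ids))
    if missing:
        raise ValueError(f"MSAA has no rows for tree leaves: {missing}")
    n_nodes = 1 + len(parent_index)
    states = np.zeros((n_nodes, msaa.n_columns), dtype=np.int8)
    col_ll = np.zeros(msaa.n_columns)
    row_of = {rid: i for i, rid in enumerate(msaa.row_ids)}
    for j in range(msaa.n_columns):
        leaf_states = {lab: int(msaa.presence[row_of[lab], j]) for lab in leaves}
        assignment, ll = joint_ml_column(tree, leaf_states, model)
        for idx, s in assignment.items():
            states[idx, j] = s
        col_ll[j] = ll
    return Reconstruction(
        tree=tree,
        column_order=list(msaa.column_order),
        states=states,
        fixed=set(),
        events=compute_events(tree, states, parent_index),
        guide_log_likelihood=float(col_ll.sum()),
        col_log_likelihood=col_ll,
        parent_index=parent_index,
        branch_length=branch_length,
        node_name=node_name,
    )


def find_contradictions(
    recon: Reconstruction, younger_cols: dict[int, np.ndarray]
) -> set[tuple[int, int]]:
    """All (parent node, column) pairs where an insertion violates the PSIO."""
    out: set[tuple[int, int]] = set()
    for child_idx, ev in recon.events.items():
        par_idx = recon.parent_index[child_idx]
        parent_state = recon.states[par_idx]
        for col in ev.insertions:
            yc = younger_cols[col]
            if yc.size and parent_state[yc].any():
                out.add((par_idx, col))
    return out


def _younger_columns(psio: PSIO, msaa: MSAA) -> dict[int, np.ndarray]:
    col = msaa.column_index()
    return {
        col[s]: np.array(sorted(col[y] for y in psio.older_than(s)), dtype=int)
        for s in msaa.column_order
    }


def enforce_psio(
    recon: Reconstruction, psio: PSIO, msaa: MSAA, model: GainLossModel
) -> Reconstruction:
    """Iteratively fix contradicting spacers at their parent nodes until the
    reconstruction respects the PSIO.  Returns a new Reconstruction; the
    input is not modified."""
    younger_cols = _younger_columns(psio, msaa)
    states = recon.states.copy()
    col_ll = recon.col_log_likelihood.copy()
    fixed: set[tuple[int, int]] = set(recon.fixed)
    events = recon.events
    leaves = {nd.taxon.label for nd in recon.tree.leaf_node_iter()}
    row_of = {rid: i for i, rid in enumerate(msaa.row_ids)}
    work = replace(recon, states=states, col_log_likelihood=col_ll, fixed=fixed, events=events)

    max_sweeps = states.shape[0] * states.shape[1] + 1
    sweeps = 0
    while True:
        contradictions = find_contradictions(work, younger_cols)
        new = contradictions - fixed
        if not new:
            break
        sweeps += 1
        if sweeps > max_sweeps:  # pragma: no cover - termination guard
            raise RuntimeError("PSIO enforcement failed to terminate")
        fixed |= new
        fixed_by_col: dict[int, frozenset[int]] = {}
        for node_idx, col in fixed:
            fixed_by_col[col] = fixed_by_col.get(col, frozenset()) | {node_idx}
        for col in {c for _, c in new}:
            leaf_states = {
                lab: int(msaa.presence[row_of[lab], col]) for lab in leaves
            }
            assignment, ll = joint_ml_column(
                work.tree, leaf_states, model, fixed_by_col[col]
            )
            for idx, s in assignment.items():
                states[idx, col] = s
            col_ll[col] = ll
        events = compute_events(work.tree, states, work.parent_index)
        work = replace(work, events=events, fixed=fixed)

    return replace(
        work,
        events=events,
        fixed=fixed,
        guide_log_likelihood=float(col_ll.sum()),
        n_enforcement_sweeps=sweeps,
    )
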