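"""Rooted trees for reconstruction: I/O, distance-based estimation, coalescent sampling.

Trees are held as :class:`dendropy.Tree` objects (forced rooted), with leaf
taxon labels equal to array IDs and branch lengths in the same time units as
the model rates.

When no tree is supplied by the user, one is estimated from a simple
pairwise distance between arrays: under polarized insertion at rate theta,
spacers private to one of two arrays accumulated since their divergence, so

    d(a, b) = (|private_a| + |private_b| + 1) / theta,

with a pseudocount of one acquisition so identical arrays keep a positive
distance, and a configured cap for pairs sharing no spacer at all.  NJ or
UPGMA then turns the matrix into a tree (NJ trees are midpoint-rooted;
negative NJ branch lengths are clamped to zero and counted).
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
import numpy as np

from .arrays import ArrayGroup, SpacerArray
from .likelihood import BDMParams

DEFAULT_DISJOINT_DISTANCE = 100.0


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    src = str(source)
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema="newick", rooting="force-rooted")
    return dendropy.Tree.get(path=src, schema="newick", rooting="force-rooted")


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def pairwise_distance(
    a: SpacerArray,
    b: SpacerArray,
    params: BDMParams,
    d_max: float = DEFAULT_DISJOINT_DISTANCE,
) -> float:
    """Private-spacer distance between two arrays (see module docstring)."""
    sa, sb = set(a.spacers), set(b.spacers)
    if not sa & sb:
        return d_max
    return (len(sa - sb) + len(sb - sa) + 1) / params.theta


def distance_matrix(
    group: ArrayGroup,
    params: BDMParams,
    d_max: float = DEFAULT_DISJOINT_DISTANCE,
) -> tuple[list[str], np.ndarray]:
    labels = group.array_ids()
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(
                group.arrays[i], group.arrays[j], params, d_max
            )
    return labels, d


def _clamp_negative_lengths(tree: dendropy.Tree) -> int:
    n = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n += 1
    return n


def estimate_tree(
    labels: list[str],
    d: np.ndarray,
    method: str = "nj",
) -> dendropy.Tree:
    """Estimate a rooted tree from a distance matrix by NJ or UPGMA.

    NJ trees are midpoint-rooted; negative NJ branch lengths are clamped to
    zero first and the count is stored as ``tree.n_clamped_edges``.
    """
    if len(labels) < 2:
        raise ValueError("tree estimation needs at least 2 labels")
    if method not in ("nj", "upgma"):
        raise ValueError(f"unknown tree method {method!r}")
    if len(labels) == 2:
        half = float(d[0, 1]) / 2.0
        tree = read_newick(f"({labels[0]}:{half},{labels[1]}:{half});")
        tree.n_clamped_edges = 0
        return tree

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{d[i, j]:.12g}" for j in range(len(labels))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    if method == "upgma":
        tree = pdm.upgma_tree()
        tree.n_clamped_edges = _clamp_negative_lengths(tree)
    else:
        tree = pdm.nj_tree()
        tree.n_clamped_edges = _clamp_negative_lengths(tree)
        tree.reroot_at_midpoint(update_bipartitions=True)
    tree.is_rooted = True
    return tree


def sample_coalescent_tree(
    n_leaves: int,
    rng: np.random.Generator | int,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Sample a Kingman coalescent genealogy for ``n_leaves`` lineages.

    With k lineages the waiting time to the next coalescence is
    Exp(k(k-1)/2); the merging pair is uniform.  Deterministic for a fixed
    seed/generator state.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if labels is None:
        labels = [f"A{i + 1}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    active: list[tuple[dendropy.Node, float]] = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        active.append((nd, 0.0))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (ni, hi), (nj, hj) = active[i], active[j]
        parent = dendropy.Node()
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = t - hi
        nj.edge.length = t - hj
        active[i] = (parent, t)
        del active[j]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = active[0][0]
    tree.is_rooted = True
    return tree


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(
        e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
    )
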