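"""Multiple Spacer Array Alignment (MSAA) and Partial Spacer Insertion Order (PSIO).

Under polarized acquisition, position within an array encodes age: the
leader-most spacer is the youngest.  Each array therefore induces a total
order on its own spacers, and combining the adjacency constraints of all
arrays yields a partial order over the group vocabulary — the PSIO, stored
as a DAG with edges ``x -> y`` meaning "x was inserted before y" (x older).

Because every column of an MSAA corresponds to one unique spacer, the
alignment is fully determined by a PSIO-consistent linear order of the
vocabulary; we build it directly by topological sort (youngest leftmost,
smallest-ID tie-break) instead of running a sequence aligner.

Conflicting insertion orders (arrays disagreeing on relative age) create
cycles.  These are resolved per strongly connected component by majority
support: intra-SCC edges supported by fewer arrays than the SCC maximum are
dropped; on a complete tie, all intra-SCC edges are dropped and the spacers
stay mutually unordered.  Resolution is reported, never silent.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .arrays import ArrayGroup


@dataclass
class PSIO:
    """Partial spacer insertion order: DAG, edge x->y = "x older than y"."""

    graph: nx.DiGraph
    support: dict[tuple[int, int], int]
    dropped_edges: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    def older_than(self, x: int) -> set[int]:
        """All spacers y with x strictly older than y (transitive closure)."""
        return nx.descendants(self.graph, x)

    def to_edge_tsv(self) -> str:
        rows = ["older\tyounger\tsupport"]
        rows += [f"{x}\t{y}\t{c}" for (x, y), c in sorted(self.support.items())
                 if self.graph.has_edge(x, y)]
        return "\n".join(rows) + "\n"


@dataclass
class MSAA:
    """Presence/absence matrix, one column per unique spacer, one row per array."""

    column_order: list[int]
    presence: np.ndarray  # shape (n_arrays, n_columns), dtype int8
    row_ids: list[str]
    decode_violations: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.column_order)

    def column_index(self) -> dict[int, int]:
        return {s: j for j, s in enumerate(self.column_order)}

    def decode_row(self, i: int) -> list[int]:
        """Spacer sequence implied by row i read along the column order."""
        return [s for s, bit in zip(self.column_order, self.presence[i]) if bit]

    def row_for(self, array_id: str) -> np.ndarray:
        return self.presence[self.row_ids.index(array_id)]

    def to_tsv(self) -> str:
        header = "array_id\t" + "\t".join(str(s) for s in self.column_order)
        rows = [header]
        for rid, row in zip(self.row_ids, self.presence):
            rows.append(rid + "\t" + "\t".join(str(int(v)) for v in row))
        return "\n".join(rows) + "\n"


def build_psio(group: ArrayGroup) -> PSIO:
    """Combine the per-array insertion orders into a single DAG.

    Each array ``[s0, s1, ..., sk]`` (s0 at the leader end, youngest)
    contributes one edge ``s_{i+1} -> s_i`` per adjacent pair.  Edge support
    counts the number of arrays inducing the edge.  Cycles are resolved by
    the majority rule described in the module docstring; conflicts never
    abort.
    """
    g = nx.DiGraph()
    support: dict[tuple[int, int], int] = {}
    for arr in group.arrays:
        seq = arr.leader_most_dedup()
        g.add_nodes_from(seq)
        for younger, older in zip(seq, seq[1:]):
            support[(older, younger)] = support.get((older, younger), 0) + 1
            g.add_edge(older, younger)

    dropped: list[tuple[int, int, int]] = []
    while True:
        sccs = [c for c in nx.strongly_connected_components(g) if len(c) > 1]
        if not sccs:
            break
        for scc in sccs:
            intra = [(u, v) for u, v in g.edges if u in scc and v in scc]
            supports = [support[e] for e in intra]
            top = max(supports)
            victims = [e for e in intra if support[e] < top]
            if not victims:  # complete tie: leave the SCC unordered
                victims = intra
            for u, v in victims:
                g.remove_edge(u, v)
                dropped.append((u, v, support[(u, v)]))
    return PSIO(graph=g, support=support, dropped_edges=dropped)


def _column_order(psio: PSIO) -> list[int]:
    """Topological order, youngest leftmost, smallest spacer ID first on ties.

    Kahn's algorithm on the age-reversed graph (edges younger -> older) with
    a min-heap makes the order deterministic.
    """
    rev = psio.graph.reverse(copy=True)
    indeg = dict(rev.in_degree())
    heap = [n for n, d in indeg.items() if d == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        n = heapq.heappop(heap)
        order.append(n)
        for _, m in rev.out_edges(n):
            indeg[m] -= 1
            if indeg[m] == 0:
                heapq.heappush(heap, m)
    if len(order) != rev.number_of_nodes():  # pragma: no cover - PSIO is acyclic
        raise RuntimeError("PSIO is not acyclic")
    return order


def build_msaa(group: ArrayGroup, psio: PSIO) -> MSAA:
    """Lay out the group as a presence matrix over a PSIO-consistent column order.

    Arrays whose (deduplicated) sequence cannot be read off the final column
    order — possible only after conflict-edge dropping — are recorded in
    ``decode_violations``; their presence rows are still filled.
    """
    order = _column_order(psio)
    col = {s: j for j, s in enumerate(order)}
    presence = np.zeros((group.n_arrays, len(order)), dtype=np.int8)
    violations: list[str] = []
    for i, arr in enumerate(group.arrays):
        seq = arr.leader_most_dedup()
        for s in seq:
            presence[i, col[s]] = 1
        decoded = [s for s in order if presence[i, col[s]]]
        if decoded != seq:
            violations.append(arr.array_id)
    return MSAA(
        column_order=order,
        presence=presence,
        row_ids=group.array_ids(),
        decode_violations=violations,
    )
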