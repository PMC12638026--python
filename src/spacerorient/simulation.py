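"""Simulation of spacer-array groups under polarized insertion + block deletion.

Groups are generated by (i) sampling a Kingman coalescent genealogy, (ii)
drawing a root array whose length approximates the stationary length
distribution of the block deletion model (Poisson with mean
theta/(rho*alpha), conditioned on at least one spacer), and (iii) evolving
the array along every branch with a Gillespie scheme: acquisitions at rate
theta prepend a fresh spacer at the leader end; deletion initiations at rate
rho per present spacer remove a geometric-length block of contiguous spacers
around a uniformly chosen seed spacer (the seed's position within the block
is uniform; blocks truncate at the array ends).  An array may go extinct,
after which only acquisitions can occur.

Each emitted group is reversed with probability 1/2 so the simulated
acquisition end is hidden from the predictor; the truth is recorded in the
manifest.  The benchmark harness replays orientation prediction over many
simulated groups and tallies correct / wrong / undetermined / exact-zero
outcomes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .arrays import ArrayGroup, SpacerArray, reverse_group
from .likelihood import BDMParams
from .orientation import (
    DECISION_NOT_DETERMINED,
    predict_orientation,
)
from .reconstruction import GainLossModel
from .trees import sample_coalescent_tree


@dataclass
class SimConfig:
    """Study conditions for one batch of simulated groups.

    Default rates (theta=15, rho=0.4, alpha=2.5) put the stationary mean
    array length at 15 spacers — mid-sized natural arrays — on coalescent
    time scales.  ``min_events`` discards groups without observed deletions,
    matching benchmark designs estimated on groups with at least one
    deletion.
    """

    params: BDMParams = field(
        default_factory=lambda: BDMParams(theta=15.0, rho=0.4, alpha=2.5)
    )
    n_leaves: int = 10
    n_groups: int = 1
    rng_seed: int = 0
    min_events: int = 1
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.min_events < 0:
            raise ValueError("min_events must be >= 0")


@dataclass
class SimEvent:
    kind: str  # "acq" or "del"
    time: float
    spacers: list[int]


@dataclass
class SimulatedGroup:
    group: ArrayGroup
    true_orientation: str  # acquisition end of the *emitted* group
    tree: dendropy.Tree
    events: dict[str, list[SimEvent]]  # branch (child node name) -> events
    n_deletion_events: int
    n_deleted_spacers: int
    n_acquisitions: int
    seed: int
    n_retries: int = 0


def sample_root_array(
    params: BDMParams, rng: np.random.Generator, id_counter: itertools.count | None = None
) -> SpacerArray:
    """Root array with length ~ Poisson(theta/(rho*alpha)) conditioned >= 1.

    Fresh spacer IDs; the leader-most (index 0) spacer is the youngest.
    """
    if id_counter is None:
        id_counter = itertools.count()
    mean = params.stationary_mean_length
    length = 0
    while length < 1:
        length = int(rng.poisson(mean))
    ids = [next(id_counter) for _ in range(length)]
    return SpacerArray(array_id="root", spacers=ids)


def evolve_branch(
    spacers: list[int],
    t: float,
    params: BDMParams,
    rng: np.random.Generator,
    id_counter: itertools.count,
    t0: float = 0.0,
) -> tuple[list[int], list[SimEvent]]:
    """Gillespie evolution of one array over a branch of length ``t``.

    Returns the evolved spacer list and the event log (times are offsets
    from ``t0``, i.e. absolute within the tree when ``t0`` is the branch's
    start height).
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    arr = list(spacers)
    events: list[SimEvent] = []
    clock = 0.0
    p_block = 1.0 / params.alpha
    while True:
        total_rate = params.theta + params.rho * len(arr)
        clock += rng.exponential(1.0 / total_rate)
        if clock >= t:
            break
        if rng.random() < params.theta / total_rate:
            new_id = next(id_counter)
            arr.insert(0, new_id)
            events.append(SimEvent("acq", t0 + clock, [new_id]))
        else:
            seed_idx = int(rng.integers(len(arr)))
            block_len = int(rng.geometric(p_block))
            offset = int(rng.integers(block_len))  # seed position within block
            start = max(0, seed_idx - offset)
            stop = min(len(arr), start + block_len)
            removed = arr[start:stop]
            del arr[start:stop]
            events.append(SimEvent("del", t0 + clock, removed))
    return arr, events


def simulate_group(
    config: SimConfig, rng: np.random.Generator | None = None, group_id: str = "sim"
) -> SimulatedGroup:
    """Simulate one group passing the overlap/min-events filters (with redraws)."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    labels = [f"A{i + 1}" for i in range(config.n_leaves)]
    for attempt in range(config.max_retries):
        tree = sample_coalescent_tree(config.n_leaves, rng, labels=labels)
        id_counter = itertools.count()
        root_arr = sample_root_array(config.params, rng, id_counter)
        heights = {}
        for nd in tree.preorder_node_iter():
            heights[nd] = (
                0.0 if nd.parent_node is None
                else heights[nd.parent_node] + nd.edge.length
            )
        arrays_at: dict = {tree.seed_node: root_arr.spacers}
        event_log: dict[str, list[SimEvent]] = {}
        k = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            k += 1
            name = nd.taxon.label if nd.taxon else f"node{k}"
            evolved, events = evolve_branch(
                arrays_at[nd.parent_node], nd.edge.length, config.params,
                rng, id_counter, t0=heights[nd.parent_node],
            )
            arrays_at[nd] = evolved
            event_log[name] = events

        leaf_arrays = []
        extinct = False
        for nd in tree.leaf_node_iter():
            if not arrays_at[nd]:
                extinct = True
                break
            leaf_arrays.append(SpacerArray(nd.taxon.label, list(arrays_at[nd])))
        if extinct:
            continue
        group = ArrayGroup(group_id=group_id, arrays=leaf_arrays)
        deletions = [e for evs in event_log.values() for e in evs if e.kind == "del"]
        acquisitions = [e for evs in event_log.values() for e in evs if e.kind == "acq"]
        if len(deletions) < config.min_events or not group.has_spacer_overlap():
            continue
        true_orientation = "forward"
        if rng.random() < 0.5:
            group = reverse_group(group)
            group.orientation_tag = "forward"  # emitted data carries no tag
            true_orientation = "reverse"
        group.validate()
        return SimulatedGroup(
            group=group,
            true_orientation=true_orientation,
            tree=tree,
            events=event_log,
            n_deletion_events=len(deletions),
            n_deleted_spacers=sum(len(e.spacers) for e in deletions),
            n_acquisitions=len(acquisitions),
            seed=config.rng_seed,
            n_retries=attempt,
        )
    raise RuntimeError(
        f"simulate_group: no acceptable group in {config.max_retries} attempts "
        f"(n_leaves={config.n_leaves}, min_events={config.min_events})"
    )


def simulate_groups(config: SimConfig) -> list[SimulatedGroup]:
    """Simulate ``config.n_groups`` groups from one seeded generator."""
    rng = np.random.default_rng(config.rng_seed)
    return [
        simulate_group(replace(config, n_groups=1), rng, group_id=f"sim{g:04d}")
        for g in range(config.n_groups)
    ]


def benchmark_accuracy(
    config: SimConfig,
    c: float = 0.0,
    use_true_tree: bool = True,
    model: GainLossModel | None = None,
    min_deletion_events: int | None = None,
) -> pd.DataFrame:
    """Run orientation prediction over simulated groups; tally the outcomes.

    Returns one row per group (decision, truth, L_ratio, event counts) with
    the summary fractions available via :func:`summarize_benchmark`.
    ``min_deletion_events`` optionally raises the per-group deletion filter
    above ``config.min_events``.
    """
    cfg = config
    if min_deletion_events is not None:
        cfg = replace(config, min_events=min_deletion_events)
    sims = simulate_groups(cfg)
    rows = []
    for sim in sims:
        res = predict_orientation(
            sim.group,
            tree=sim.tree if use_true_tree else None,
            params=cfg.params,
            model=model,
            c=c,
        )
        if res.L_ratio == 0.0:
            outcome = "zero"
        elif res.decision == DECISION_NOT_DETERMINED:
            outcome = "not_determined"
        elif res.decision == sim.true_orientation:
            outcome = "correct"
        else:
            outcome = "wrong"
        rows.append(
            {
                "group_id": sim.group.group_id,
                "true_orientation": sim.true_orientation,
                "decision": res.decision,
                "outcome": outcome,
                "L_ratio": res.L_ratio,
                "n_deletion_events": sim.n_deletion_events,
                "n_deleted_spacers": sim.n_deleted_spacers,
                "n_acquisitions": sim.n_acquisitions,
            }
        )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> dict[str, float]:
    """Fractions of correct / wrong / not_determined / exact-zero outcomes."""
    n = len(table)
    counts = table["outcome"].value_counts()
    return {
        "n_groups": n,
        "frac_correct": counts.get("correct", 0) / n,
        "frac_wrong": counts.get("wrong", 0) / n,
        "frac_not_determined": counts.get("not_determined", 0) / n,
        "frac_zero": counts.get("zero", 0) / n,
    }


def manifest_tsv(sims: list[SimulatedGroup]) -> str:
    rows = ["group_id\tseed\ttrue_orientation\tn_deletion_events\tn_acquisitions"]
    for s in sims:
        rows.append(
            f"{s.group.group_id}\t{s.seed}\t{s.true_orientation}"
            f"\t{s.n_deletion_events}\t{s.n_acquisitions}"
        )
    return "\n".join(rows) + "\n"
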