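"""Spacer-array group data model and I/O.

A CRISPR spacer array is modelled as an ordered sequence of integer spacer
identifiers with the *leader* end (where new spacers are acquired under the
forward-orientation hypothesis) at position 0.  Groups of related arrays are
the unit of analysis: orientation prediction exploits the overlap in spacer
content between arrays of a group.

Two input dialects are supported: a plain-text token format (one array per
line: ``array_id<TAB>token token ...``, ``#`` starts a comment) and one FASTA
file per array with the spacer DNA sequences in array order.  In both cases
spacers are relabelled to dense non-negative integers; identical DNA
sequences (case-insensitive exact match) receive the same identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class SpacerArray:
    """One spacer array: ordered spacer IDs, leader-most first."""

    array_id: str
    spacers: list[int]
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError(f"array {self.array_id!r}: empty spacer list")
        if any(s < 0 for s in self.spacers):
            raise ValueError(f"array {self.array_id!r}: negative spacer ID")

    def __len__(self) -> int:
        return len(self.spacers)

    def duplicated_spacers(self) -> set[int]:
        """Spacer IDs occurring more than once within this array."""
        seen: set[int] = set()
        dups: set[int] = set()
        for s in self.spacers:
            if s in seen:
                dups.add(s)
            seen.add(s)
        return dups

    def leader_most_dedup(self) -> list[int]:
        """Spacer sequence with repeats collapsed to the leader-most occurrence."""
        seen: set[int] = set()
        out: list[int] = []
        for s in self.spacers:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out


@dataclass
class ArrayGroup:
    """A group of related spacer arrays sharing one spacer vocabulary."""

    group_id: str
    arrays: list[SpacerArray]
    orientation_tag: str = FORWARD
    diagnostics: dict = field(default_factory=dict)

    @property
    def vocabulary(self) -> set[int]:
        return set().union(*(set(a.spacers) for a in self.arrays))

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    def has_spacer_overlap(self) -> bool:
        """True if at least one spacer occurs in two or more arrays."""
        counts: dict[int, int] = {}
        for a in self.arrays:
            for s in set(a.spacers):
                counts[s] = counts.get(s, 0) + 1
        return any(c >= 2 for c in counts.values())

    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    def validate(self) -> dict:
        """Populate and return group diagnostics (size, overlap, duplications)."""
        dups = {a.array_id: sorted(a.duplicated_spacers()) for a in self.arrays}
        self.diagnostics.update(
            single_array=self.n_arrays < 2,
            non_informative=not self.has_spacer_overlap(),
            duplications={k: v for k, v in dups.items() if v},
        )
        return self.diagnostics


def _relabel(token_arrays: Sequence[tuple[str, Sequence[str]]]) -> tuple[list[SpacerArray], dict[str, int]]:
    mapping: dict[str, int] = {}
    arrays = []
    for array_id, tokens in token_arrays:
        ids = []
        for tok in tokens:
            if tok not in mapping:
                mapping[tok] = len(mapping)
            ids.append(mapping[tok])
        arrays.append(SpacerArray(array_id=array_id, spacers=ids))
    return arrays, mapping


def read_token_group(path: str | Path, group_id: str | None = None) -> tuple[ArrayGroup, dict[str, int]]:
    """Read a token-format group file.

    Returns the group together with the token -> dense-integer mapping
    (first-seen order).  Raises ``ValueError`` on an empty file, a duplicate
    array_id, or a line without spacer tokens.
    """
    path = Path(path)
    raw: list[tuple[str, list[str]]] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: array line needs at least one spacer token")
        array_id, tokens = fields[0], fields[1:]
        if array_id in seen_ids:
            raise ValueError(f"{path}:{lineno}: duplicate array_id {array_id!r}")
        seen_ids.add(array_id)
        raw.append((array_id, tokens))
    if not raw:
        raise ValueError(f"{path}: no arrays")
    arrays, mapping = _relabel(raw)
    for a in arrays:
        a.source = str(path)
    group = ArrayGroup(group_id=group_id or path.stem, arrays=arrays)
    group.validate()
    return group, mapping


def read_fasta_group(paths: Iterable[str | Path], group_id: str | None = None) -> tuple[ArrayGroup, dict[int, str]]:
    """Read one FASTA file per array; records in array order, leader-most first.

    Identical sequences (uppercased exact match) across all files share one
    spacer ID.  Returns the group and the ID -> sequence table.
    """
    paths = [Path(p) for p in paths]
    raw: list[tuple[str, list[str]]] = []
    for p in paths:
        records = list(SeqIO.parse(str(p), "fasta"))
        if not records:
            raise ValueError(f"{p}: no FASTA records")
        seqs = []
        for rec in records:
            s = str(rec.seq).upper()
            if not s:
                raise ValueError(f"{p}: empty record {rec.id!r}")
            seqs.append(s)
        raw.append((p.stem, seqs))
    arrays, mapping = _relabel(raw)
    for a, p in zip(arrays, paths):
        a.source = str(p)
    group = ArrayGroup(group_id=group_id or "fasta_group", arrays=arrays)
    group.validate()
    return group, {v: k for k, v in mapping.items()}


def reverse_group(group: ArrayGroup) -> ArrayGroup:
    """Reverse every array's spacer sequence and toggle the orientation tag."""
    rev = ArrayGroup(
        group_id=group.group_id,
        arrays=[
            SpacerArray(a.array_id, list(reversed(a.spacers)), a.source)
            for a in group.arrays
        ],
        orientation_tag=REVERSE if group.orientation_tag == FORWARD else FORWARD,
    )
    rev.validate()
    return rev


def write_token_group(group: ArrayGroup, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# group {group.group_id} orientation={group.orientation_tag}"]
    for a in group.arrays:
        lines.append(a.array_id + "\t" + " ".join(str(s) for s in a.spacers))
    path.write_text("\n".join(lines) + "\n")


def write_mapping_tsv(mapping: dict, path: str | Path) -> None:
    """Write a spacer_id <-> token/sequence table (two TSV columns)."""
    path = Path(path)
    rows = ["spacer_id\ttoken_or_sequence"]
    # accept either token->id or id->sequence orientation of the dict
    items = sorted(
        ((v, k) if isinstance(v, int) else (k, v) for k, v in mapping.items())
    )
    rows += [f"{i}\t{t}" for i, t in items]
    path.write_text("\n".join(rows) + "\n")
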