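"""Orientation prediction by forward/reverse likelihood comparison.

The acquisition orientation of a group of related spacer arrays is inferred
by reconstructing the group's ancestral insertion/deletion history twice —
once in the orientation the data arrived in ("forward") and once with every
array's spacer sequence reversed — scoring both reconstructions under the
block deletion model, and comparing

    L_ratio = log L_forward - log L_reverse.

If |L_ratio| > c the better-supported orientation is returned; otherwise the
likelihoods are too close and the result is "not determined".  The default
threshold c = 5 is conservative: it demands more than two orders of
magnitude (e^5) between the forward and reverse likelihoods.

An exactly zero ratio arises for groups with no reconstructed events or a
forward/reverse-symmetric event structure; because the score is blind to
spacer labels, such groups cannot carry orientation signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .alignment import build_msaa, build_psio
from .arrays import ArrayGroup, reverse_group
from .likelihood import BDMParams, reconstruction_log_likelihood
from .reconstruction import (
    GainLossModel,
    Reconstruction,
    enforce_psio,
    guide_reconstruction,
)
from .trees import distance_matrix, estimate_tree

ZERO_TOL = 1e-9

DECISION_FORWARD = "forward"
DECISION_REVERSE = "reverse"
DECISION_NOT_DETERMINED = "not_determined"

TSV_COLUMNS = [
    "group_id", "n_arrays", "L_forward", "L_reverse", "L_ratio",
    "threshold_c", "decision", "deletion_count_forward",
    "deletion_count_reverse", "deletion_count_difference", "zero_ratio_reason",
]


@dataclass
class OrientationResult:
    group_id: str
    L_forward: float
    L_reverse: float
    L_ratio: float
    threshold_c: float
    decision: str
    n_arrays: int
    deletion_count_forward: int = 0
    deletion_count_reverse: int = 0
    zero_ratio_reason: str | None = None
    recon_forward: Reconstruction | None = field(default=None, repr=False)
    recon_reverse: Reconstruction | None = field(default=None, repr=False)

    @property
    def deletion_count_difference(self) -> int:
        return abs(self.deletion_count_forward - self.deletion_count_reverse)

    def to_row(self) -> dict:
        return {
            "group_id": self.group_id,
            "n_arrays": self.n_arrays,
            "L_forward": self.L_forward,
            "L_reverse": self.L_reverse,
            "L_ratio": self.L_ratio,
            "threshold_c": self.threshold_c,
            "decision": self.decision,
            "deletion_count_forward": self.deletion_count_forward,
            "deletion_count_reverse": self.deletion_count_reverse,
            "deletion_count_difference": self.deletion_count_difference,
            "zero_ratio_reason": self.zero_ratio_reason or "",
        }


def reconstruct_oriented(
    group: ArrayGroup,
    tree: dendropy.Tree | None,
    params: BDMParams,
    model: GainLossModel,
    tree_method: str = "nj",
) -> tuple[Reconstruction, float]:
    """Full single-orientation pipeline: PSIO -> MSAA -> [tree] -> guide ->
    PSIO enforcement -> BDM score."""
    psio = build_psio(group)
    msaa = build_msaa(group, psio)
    if tree is None:
        labels, d = distance_matrix(group, params)
        tree = estimate_tree(labels, d, method=tree_method)
    recon = guide_reconstruction(msaa, tree, model)
    recon = enforce_psio(recon, psio, msaa, model)
    return recon, reconstruction_log_likelihood(recon, params)


def decide(l_ratio: float, c: float) -> str:
    if l_ratio > c:
        return DECISION_FORWARD
    if l_ratio < -c:
        return DECISION_REVERSE
    return DECISION_NOT_DETERMINED


def predict_orientation(
    group: ArrayGroup,
    tree: dendropy.Tree | None = None,
    params: BDMParams | None = None,
    model: GainLossModel | None = None,
    c: float = 5.0,
    tree_method: str = "nj",
) -> OrientationResult:
    """Predict the acquisition orientation of a group of spacer arrays.

    A user-supplied ``tree`` is used unchanged for both orientation runs (it
    is independent of spacer order), making the ratio exactly antisymmetric
    under input reversal.  Without one, a tree is re-estimated from the
    arrays for each orientation separately, since the distances depend on
    the assumed orientation.  Identical model/BDM parameters are used for
    both runs so the ratio is a meaningful likelihood comparison.
    """
    if params is None:
        params = BDMParams()
    if model is None:
        model = GainLossModel()
    if c < 0:
        raise ValueError("threshold c must be >= 0")
    if group.n_arrays < 2:
        raise ValueError(
            "orientation prediction requires a group of at least 2 arrays"
        )
    if not group.has_spacer_overlap():
        return OrientationResult(
            group_id=group.group_id,
            L_forward=0.0, L_reverse=0.0, L_ratio=0.0,
            threshold_c=c, decision=DECISION_NOT_DETERMINED,
            n_arrays=group.n_arrays,
            zero_ratio_reason="no spacer overlap",
        )

    rev = reverse_group(group)
    recon_f, l_forward = reconstruct_oriented(group, tree, params, model, tree_method)
    recon_r, l_reverse = reconstruct_oriented(rev, tree, params, model, tree_method)

    l_ratio = l_forward - l_reverse
    zero_reason = None
    if abs(l_ratio) < ZERO_TOL:
        l_ratio = 0.0
        if recon_f.total_insertions == 0 and recon_f.total_deleted_spacers == 0:
            zero_reason = "no reconstructed events"
        else:
            zero_reason = "symmetric reconstructions"

    return OrientationResult(
        group_id=group.group_id,
        L_forward=l_forward,
        L_reverse=l_reverse,
        L_ratio=l_ratio,
        threshold_c=c,
        decision=decide(l_ratio, c),
        n_arrays=group.n_arrays,
        deletion_count_forward=recon_f.total_deleted_spacers,
        deletion_count_reverse=recon_r.total_deleted_spacers,
        zero_ratio_reason=zero_reason,
        recon_forward=recon_f,
        recon_reverse=recon_r,
    )


def deletion_count_difference(
    recon_f: Reconstruction, recon_r: Reconstruction
) -> int:
    """|spacers deleted forward - spacers deleted reverse| — a diagnostic that
    grows with |L_ratio| and supports the choice of threshold."""
    return abs(recon_f.total_deleted_spacers - recon_r.total_deleted_spacers)


def results_to_tsv(results: list[OrientationResult], header_meta: dict | None = None) -> str:
    lines = [f"# {k} = {v}" for k, v in (header_meta or {}).items()]
    lines.append("\t".join(TSV_COLUMNS))
    for r in results:
        row = r.to_row()
        lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
    return "\n".join(lines) + "\n"
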