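"""Block-deletion-model (BDM) scoring of reconstructions.

The BDM describes spacer-array turnover by polarized acquisition at the
leader end at rate ``theta`` and deletion of contiguous blocks: deletions
initiate at rate ``rho`` per present spacer and remove a block whose length
is geometric with mean ``alpha``.

A reconstruction is scored branch by branch from its event lists alone:

    log L(branch) = log Pois(k_ins; theta * t)
                  + log Pois(J; rho * n_parent * t)
                  + sum_j log Geom(l_j; p = 1 / alpha)

where ``k_ins`` is the number of insertion events on the branch, ``J`` the
number of deletion blocks with lengths ``l_j``, ``n_parent`` the number of
spacers present at the parent node (the deletion opportunities), and ``t``
the branch length.  The geometric distribution is supported on {1, 2, ...}.
The root array is treated as given and contributes no term.

The score depends only on event counts, block lengths, branch lengths and
parent sizes — never on spacer identities.  This label-blindness is what
makes the forward/reverse log-likelihood ratio of a structurally symmetric
group exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .reconstruction import Reconstruction


def _log_poisson_pmf(k: int, mu: float) -> float:
    # closed form; scalar and hot (the orientation ratio evaluates it per branch)
    if mu == 0.0:
        return 0.0 if k == 0 else -math.inf
    return k * math.log(mu) - mu - math.lgamma(k + 1)


def _log_geometric_pmf(k: int, p: float) -> float:
    # support {1, 2, ...}
    if p == 1.0:
        return 0.0 if k == 1 else -math.inf
    return (k - 1) * math.log1p(-p) + math.log(p)


@dataclass
class BDMParams:
    """BDM rate parameters.

    theta: leader-end acquisitions per unit time (> 0).
    rho:   deletion initiations per present spacer per unit time (> 0).
    alpha: mean deletion-block length in spacers (>= 1).

    The defaults are calibration placeholders exposed for configuration, not
    empirical estimates.
    """

    theta: float = 10.0
    rho: float = 0.3
    alpha: float = 2.5

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.rho <= 0:
            raise ValueError("theta and rho must be positive")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1 (mean block length)")

    @property
    def stationary_mean_length(self) -> float:
        """Mean array length at insertion/deletion balance, theta/(rho*alpha)."""
        return self.theta / (self.rho * self.alpha)


def branch_log_likelihood(
    n_insertions: int,
    deletion_block_lengths: Sequence[int],
    parent_size: int,
    t: float,
    params: BDMParams,
) -> float:
    """Log-likelihood of one branch's events under the BDM (see module docstring)."""
    if t < 0 or not math.isfinite(t):
        raise ValueError(f"branch length must be finite and >= 0, got {t}")
    n_blocks = len(deletion_block_lengths)
    if t == 0.0:
        return 0.0 if (n_insertions == 0 and n_blocks == 0) else -math.inf
    ll = _log_poisson_pmf(n_insertions, params.theta * t)
    ll += _log_poisson_pmf(n_blocks, params.rho * parent_size * t)
    p = 1.0 / params.alpha
    for length in deletion_block_lengths:
        ll += _log_geometric_pmf(length, p)
    return ll


def reconstruction_log_likelihood(recon: "Reconstruction", params: BDMParams) -> float:
    """Sum of branch log-likelihoods over all non-root branches."""
    total = 0.0
    for child_idx, ev in recon.events.items():
        parent_idx = recon.parent_index[child_idx]
        total += branch_log_likelihood(
            n_insertions=len(ev.insertions),
            deletion_block_lengths=[len(b) for b in ev.deletion_blocks],
            parent_size=int(recon.states[parent_idx].sum()),
            t=recon.branch_length[child_idx],
            params=params,
        )
    return total


def branch_score_table(recon: "Reconstruction", params: BDMParams) -> str:
    """Per-branch scoring breakdown as TSV."""
    rows = ["branch_child\tn_insertions\tn_deletion_blocks\tdeleted_spacers\tparent_size\tt\tlog_likelihood"]
    for child_idx, ev in sorted(recon.events.items()):
        parent_idx = recon.parent_index[child_idx]
        lens = [len(b) for b in ev.deletion_blocks]
        ll = branch_log_likelihood(
            len(ev.insertions), lens, int(recon.states[parent_idx].sum()),
            recon.branch_length[child_idx], params,
        )
        rows.append(
            f"{recon.node_name[child_idx]}\t{len(ev.insertions)}\t{len(lens)}"
            f"\t{sum(lens)}\t{int(recon.states[parent_idx].sum())}"
            f"\t{recon.branch_length[child_idx]:.6g}\t{ll:.6f}"
        )
    return "\n".join(rows) + "\n"
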