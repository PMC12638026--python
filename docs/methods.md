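# Methods

## The inference problem

A CRISPR array is an ordered sequence of spacers. Under polarized
acquisition, new spacers enter at the leader end only, so an array is a
stack: position correlates with age. Spacers are also lost, typically in
contiguous blocks. Given several related arrays whose true leader end is
unknown (but assumed to be the *same* end in all arrays of the group), we
ask which of the two reading directions is the acquisition direction.

The signal is asymmetry of the implied history. In the correct orientation,
differences between related arrays decompose into recent leader-end gains
private to each lineage plus block deletions of older spacers. In the
reversed orientation the same observations force implausible events —
ancient spacers appearing distally, fragmented deletions — and the
reconstruction likelihood drops. The decision statistic is the difference of
reconstruction log-likelihoods, `L_ratio = log L_fwd − log L_rev`.

## Data structures

**Spacer labels.** Spacers are dense integer IDs. From token files, tokens
are relabeled by first appearance; from FASTA, identical uppercased DNA
sequences share an ID (exact match only — fuzzy cross-genome spacer
clustering is a data-preparation concern outside this package). Duplicate
IDs within one array are collapsed to the leader-most occurrence for
order-dependent structures and reported as a duplication diagnostic; they do
not abort analysis.

**PSIO.** Each array `[s0, s1, …, sk]` (leader first) asserts that each
spacer is older than its leader-side neighbour, contributing edges
`s_{i+1} → s_i` ("older → younger"). The union over arrays is a DAG unless
arrays disagree. Disagreements (cycles) are resolved per strongly connected
component by majority support — edges induced by fewer arrays than the
within-component maximum are dropped; a complete tie drops all component
edges, leaving those spacers mutually unordered. Every dropped edge is
reported. This is a least-commitment rule for data the model does not
generate (true polarized histories are conflict-free).

**MSAA.** Because each column is one unique spacer, the alignment is fully
determined by any linear order of the vocabulary consistent with every
array, i.e. a linear extension of the PSIO, youngest leftmost. We build it
by Kahn topological sort with a smallest-ID-first heap, giving a
deterministic layout, instead of running a sequence aligner over the
integer-labeled arrays — the end product is the same object. Arrays that
cannot be read off the final order (possible only after conflict-edge
dropping) are reported; downstream reconstruction uses presence only.

## Reconstruction

**Guide step.** Each column evolves independently on the rooted tree under
a 2-state continuous-time chain with gain rate g, loss rate l, transition
probabilities in closed form, and root prior at stationarity. The jointly
most likely internal assignment is computed exactly by the Pupko
max-product dynamic program (one table per node keyed by parent state,
backtracking from the root). Ties prefer absence, implying fewer events.
Defaults g = 1e-3, l = 1.0: a near-zero gain rate encodes the polarized
premise that a given unique spacer arises once — convergent gains should
essentially never be reconstructed; the loss scale is arbitrary since only
relative magnitudes shape the argmax. The guide model is a scaffold, not
the scoring model.

**Insertion-order enforcement.** The guide, being column-independent, can
insert an old spacer on a branch below a node that already carries a
younger spacer — an invalid polarized history. Such contradictions are
found by scanning all branches (insertion of x into v counts as
contradictory when the parent u holds any y with x ≺ y in the PSIO's
transitive closure); every contradicting spacer is fixed present at its
parent node, all affected columns are recomputed under those hard
constraints, and the scan repeats. Fixes only accumulate and a fixed
insertion can only re-emerge strictly closer to the root, so the loop
terminates (bounded by nodes × columns; in the worst case contradicting
spacers are acquired at the root). Contradictions found in one sweep are
fixed as a batch — column independence makes the result identical to
one-at-a-time fixing up to sweep count, at far fewer recomputations.

**Events.** Insertions are columns present in the child but not the parent.
Deletions are grouped into maximal blocks contiguous *in the parent's
realized array*: columns absent at the parent cannot separate a block,
since they were not present to break contiguity.

## Block-deletion-model score

Each branch is scored from its event summary alone: Poisson(θt) for the
insertion count, Poisson(ρ·n_parent·t) for the number of deletion blocks
(n_parent = spacers present at the parent, the deletion opportunities), and
Geometric(1/α) on {1, 2, …} for each block length. The root array is taken
as given (no term). Defaults θ = 10, ρ = 0.3, α = 2.5 are exposed
configuration placeholders on the scale of natural arrays (stationary mean
length θ/(ρα) ≈ 13 spacers), not empirical estimates; because both
orientations are scored with identical parameters, the ratio is fairly
insensitive to their exact values. The factorization is deliberately
label-blind: only counts, lengths, branch lengths and parent sizes enter.
This yields two structural facts used throughout the tests: relabeling
invariance, and `L_ratio = 0` exactly for groups whose event structure is
reversal-symmetric.

A consequence worth naming: at θt > 1 the Poisson term *rewards* additional
insertions, so the unconstrained maximum of this score over all state
assignments can degenerate into re-gaining shared spacers independently on
many branches. Valid polarized histories exclude this — every acquisition
mints a fresh spacer, so each column originates exactly once (at the root
or on a single branch). The two-step reconstruction enforces that
implicitly through its gain-averse guide. The exhaustive oracle used in the
tests therefore enumerates assignments under both the order constraint and
single origin per spacer, and compares in the regime where all event means
are ≤ 1 (θ = 1, ρ = 1, α = 2 on branches ≈ 0.5), where adding any spurious
event strictly costs likelihood.

## Trees

A user tree (rooted Newick, leaf labels = array IDs) is used unchanged for
both orientations; the ratio is then exactly antisymmetric under input
reversal. Without one, a tree is estimated per orientation from pairwise
distances `d(a,b) = (|private_a| + |private_b| + 1)/θ` — private spacers
are the arrivals since divergence under polarized insertion; the
pseudocount keeps identical arrays at positive distance; disjoint pairs get
a configured cap (default 100). NJ (midpoint-rooted, negative branch
lengths clamped to zero and counted) or UPGMA via dendropy. This distance
is a declared simple stand-in adequate for ordering splits; users with
trusted genome trees should supply them.

## Simulator

Trees are Kingman coalescent genealogies (waiting time Exp(k(k−1)/2) at k
lineages, uniform pair merges). The root array length is Poisson(θ/(ρα))
conditioned ≥ 1 — a rough stationary approximation. Along each branch a
Gillespie scheme alternates acquisitions (rate θ, fresh ID prepended at the
leader) and deletion initiations (rate ρ per present spacer): a uniformly
chosen seed spacer, a Geometric(1/α) block length, the seed's position
within the block uniform, truncated at array ends. Arrays may go extinct
and regrow. Emitted groups are reversed with probability 1/2 (truth
recorded); groups with an extinct leaf, no spacer overlap, or fewer than
`min_events` deletion events (default 1) are redrawn with bounded retries.

Default simulation rates θ = 15, ρ = 0.4, α = 2.5 put the stationary mean
array length at 15 spacers on coalescent time scales — mid-sized arrays
with substantial but not saturating turnover. Benchmarks use 200 groups of
10 arrays (or 100 groups filtered to ≥ 5 deletion events for the
clear-signal condition); these sizes give sub-minute runs on one CPU with
binomial standard errors under 2 percentage points.

What the simulator emulates — and does not. It generates exactly the
process the scoring model assumes, so benchmark accuracy (~100% at c = 0
with true trees) demonstrates correctness of the machinery, not real-data
performance: real groups add mis-clustered spacers, duplications,
rearrangements, mixed-orientation groups, horizontal array exchange, and
trees estimated from finite genome data. Threshold calibration on real
collections remains the user's responsibility; the default c = 5 is a
conservative choice meaning e^5 ≈ 150-fold likelihood separation.

## Numerical and degenerate-input choices

- All likelihoods in log space; impossible transitions at t = 0 use −inf
  (a zero-length branch with events scores −inf, without events 0).
- `|L_ratio| < 1e-9` is reported as exactly 0 with a reason
  (`no reconstructed events` / `symmetric reconstructions` /
  `no spacer overlap`) so floating-point noise never masquerades as signal.
- Determinism everywhere: smallest-ID tie-breaks in the topological sort,
  prefer-absent ties in the DP, a single seeded generator threaded through
  all simulation.
- Groups of fewer than 2 arrays are rejected; groups without any shared
  spacer return `not_determined` without reconstruction.
- Palindromic/duplicated spacers are diagnosed, deduplicated leader-most,
  and never abort.

## Known limitations

- The BDM score is a simplified event-count factorization; an exact
  fragment-placement likelihood could sharpen ratios for heavily overlapping
  deletions. The scoring interface is a single function to allow swapping.
- Spacer identity is exact-match; sequencing error or trimmed spacers
  fragment the vocabulary and dilute overlap.
- Per-orientation tree estimation breaks exact antisymmetry of the ratio
  (documented; user trees restore it) and can misorient groups with very few
  events.
- The per-array decision is the group decision; mixed-orientation groups
  violate the model's premise and are not detected.
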