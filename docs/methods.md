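# Methods

This note documents the models, parameter choices and numerical
conventions behind `forumlens`, and what the synthetic-archive tests do
and do not demonstrate.

## Data model and inclusion rules

The unit of observation is a *comment event*: author, forum, thread,
UTC timestamp, body. Archives are JSON lines, one comment per line, with
a configurable field mapping (defaults match public Reddit comment
dumps: `author`, `subreddit`, `link_id`, `created_utc`, `body`). The
initial post of a thread is absent from comment archives, so a thread is
simply the set of comments sharing a thread id.

Inclusion rules applied by `ingest`:

- **Date window.** Whole calendar months in UTC, both ends inclusive
  (default `2017-03` .. `2018-02`, a one-year window). A record is kept
  when its timestamp lies between the first second of the start month
  and the last second of the end month.
- **Excluded accounts.** `AutoModerator` (a platform service account)
  and `[deleted]` (the placeholder for removed accounts) are dropped
  before any counting and can never appear in downstream structures.
  Comparison is exact and case-sensitive: commenter names are
  case-sensitive identities. Forum names, by contrast, are compared
  case-insensitively throughout (display names vary in case).
- **Forum discovery.** Case-insensitive substring match of search terms
  over forum name and short description; private forums and a manual
  exclusion list (topically unrelated hits) are removed. Substring
  matching over the short description is a deliberate default — the
  alternative (whole-word) is stricter than how forum names concatenate
  words.
- **Size floor.** Forums with fewer than `min_commenters` (default 500)
  distinct included commenters are dropped.

Malformed archive lines are skipped with a warning and counted rather
than aborting the run: multi-gigabyte dumps routinely contain a few bad
lines, and a hard failure hours into a parse helps no one.

## Overlap network

Edge weights are the mean of the two directed overlap proportions (see
README). Conventions:

- The diagonal is zero: a forum's overlap with itself is not an edge.
- No pruning before community detection (`min_weight = 0`, exclusive).
  A display threshold such as 0.25 is a rendering choice only; it is
  exposed in configuration for sensitivity analysis.
- Graphs preserve isolated nodes, and edge weights are carried
  bit-exactly from the matrix.

## Walktrap

The implementation follows the random-walk agglomeration recipe:
transition matrix `P = D^-1 W`, made lazy (`(I + P)/2`), raised to the
`t`-th power (default `t = 4`, the algorithm's customary default;
configurable). The distance between nodes or communities is the
Euclidean distance between their `t`-step walk distributions with each
coordinate down-weighted by the weighted degree of the target node.
Agglomeration starts from singletons and at each step performs the
*adjacent* merge minimizing the Ward-style increase in mean squared
node-to-community distance, `|C1||C2|/(|C1|+|C2|) · r²/n`; merged
communities carry the member-average of their nodes' distributions.

The laziness deserves a note: with the bare kernel `P = D^-1 W`, a
network containing a near-bipartite block — e.g. two forums tied by one
strong edge, a structure that planted two-forum communities produce
routinely — has oscillating even-step distributions, and cross-block
distances can collapse below within-block ones, merging across
communities first. The lazy walk is the standard aperiodicity remedy; it
is scale-invariant in the weights and leaves distances on structured
graphs essentially unchanged. With it, the implementation returns
partitions identical to the independent igraph reference implementation
on every structured fixture in the test suite (planted-block graphs with
random block counts, sizes and generic weights; clique barbells). On
structure-free dense random graphs the two implementations can order
near-tied merges differently — there the published recipe's outcome is
dominated by smoothing conventions, and no implementation-independent
expected partition exists; the agreement suite therefore tests random
*modular* graphs.

The final partition is the dendrogram cut maximizing weighted Newman
modularity, evaluated at every level from all-singletons to the root;
ties prefer fewer communities. Merge-cost ties break on the smallest
(lexicographic) community-id pair, with leaves numbered 0..n-1 in sorted
node-label order — this makes runs reproducible across platforms.
Disconnected graphs are handled per component and the component
dendrograms concatenated (`n_components` flags it); community detection
on overlap matrices routinely meets isolated forums in synthetic data.

## Recovery focus

A thread counts when any of its comments contains any configured term
(default: *recovery, recover, recovers, recovered, recovering*) as a
whole word, case-insensitively, with words delimited by non-alphanumeric
characters (so underscores delimit). Whole-word matching is forced by
the term list itself: the list enumerates inflections explicitly, which
substring matching would make redundant ("recover" would subsume the
rest) and false-positive-prone ("irrecoverable"). The thread's missing
initial post is not searched — it is not in comment archives.

Percentages are `100 · threads_with_term / threads_total` rounded
half-up to two decimals; a forum with zero threads is an error, not a
zero. All percentages in the package go through one shared
decimal-arithmetic rounding routine, so reports and tests agree to the
digit.

## Ancillary profiling

- **Inclusion rule.** The minimum contributor count is the smallest
  integer `k` with `k/n ≥ 1%` — the ceiling of 1% of the subtype size.
  The ceiling construction is what reproduces integer thresholds
  consistently across subtype sizes.
- **Dual ranking.** Rank 1 is the largest value on each criterion; ties
  receive fractional (average) ranks, which keeps mean ranks on a stable
  scale. The selection key is the *numerically smallest* mean rank:
  "top" forums are those best on both criteria. Output order is mean
  rank ascending, forum name as the deterministic tie-break.
- **Top-K.** Default 50. Fewer candidates than `K` returns all with a
  warning.
- **Restriction.** Overlaps among selected forums are computed after
  intersecting each forum's commenters with the subtype's, making the
  weights invariant to commenters unrelated to the subtype. Each
  ancillary forum's total-commenter denominator is computed after the
  global date/author filters, consistent with every other count in the
  pipeline.
- **Subtype floor.** Profiling skips subtypes below
  `min_subtype_commenters` (default 1000) with a log entry.

## Overlap accounting

Venn partitions classify every commenter in the union of the community
sets by the exact subset of communities they posted in; the `2^k − 1`
region counts are disjoint and sum to the union size (asserted as a
property test). Rendering is out of scope — the normative output is the
region-count table. Two-group summaries (only-A / only-B / both) and
participation percentages use the same half-up two-decimal routine.
Accounts whose name contains "bot" (case-insensitive substring) are
flagged and summarized (count share plus mean/sample-SD/median/min/max
of their comment counts) but never filtered: heavier bot screening risks
removing real users, so flagging informs interpretation only.

## Synthetic archive generator

The generator emulates the archive schema with planted ground truth:

- **Community structure.** Each commenter has a home community, is
  active in each other community with probability `ε` (default 0.05),
  and posts in each forum of an active community with probability
  `p_member` (default 0.9, at least one home forum guaranteed). Crossing
  at the *community* level (not per forum) matters: a subtype commenter
  who visits an ancillary community contributes to most of its forums,
  which is what makes planted ancillary structure recoverable from
  restricted overlaps, as in real co-commenting behaviour.
- **Activity.** Comments per (commenter, forum) are `1 + (Zipf(a) − 1)`
  with `a = 2.5`, capped at 50 — a heavy-tailed skew with minimum one
  comment, mimicking real commenting behaviour where a single comment is
  a commenter's whole record.
- **Text.** Bodies are filler words from a term-free vocabulary (which
  deliberately includes "irrecoverable" to exercise the whole-word
  rule); each comment carries a recovery term with the forum's
  configured rate `ρ`.
- **Noise.** A configurable fraction of bot-named accounts (ordinary
  behaviour, distinctive names), plus `AutoModerator` and `[deleted]`
  records. Excluded-account noise is emitted only into threads that
  already hold a regular comment and with term-free bodies, so the
  ground truth stays record-exact for the post-filter archive.
- **Determinism.** One `numpy` generator seeded from the config; the
  same config and seed produce a byte-identical archive.

What the generator does *not* model: temporal bursts, textual realism
beyond injected keywords, commenter-level activity correlations between
forums of a community beyond membership, multiple accounts per person.
Passing the planted-recovery tests therefore shows the pipeline
correctly inverts this generative model at realistic sizes and noise
levels — not that real forum populations are this cleanly separable.

## Problem sizes in the test and acceptance suites

Planted-recovery checks run at 3 communities × 5 forums with 3000
commenters (about 27k records per seed, 10 seeds) for subtype discovery,
and a 1200-commenter subtype with two 3-forum ancillary communities for
profiling. Exhaustive oracles (all set partitions, brute-force
modularity) run on graphs of up to 8 nodes; reference-implementation
agreement on 20+ random modular graphs of 6–25 nodes. These sizes make
each oracle exact and the whole suite quick while leaving every
statistic at full precision; the corpus-scale counts printed in archive
studies (tens of thousands of commenters over hundreds of forums) are
inputs the pipeline accepts but are not reproduced in tests.

## Known limitations

- No deduplication of people across accounts and no bot removal: the
  former underestimates overlap, the latter can overestimate it; both
  are reported, not corrected.
- Search-term forum discovery depends on the quality of forum
  descriptions; the manual exclusion list is the only guard against
  false positives.
- Community detection is walktrap-only by design; no consensus over
  alternative algorithms.
- The manual steps (subtype labels, community topic labels) are
  file-mediated hooks; the pipeline never invents labels.
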