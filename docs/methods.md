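# Methods

## Network construction

A corpus is a set of boards (threads): a header (board id, author, time,
title) plus ordered comments, each with a commenter, a timestamp, and one of
three reaction marks (推 like, 噓 boo, → neutral). Boards carry one stance
label from {P, H, A, neutral, irrelevant}; neutral and irrelevant boards are
excluded before network construction. Labels are consumed as input (two-rater
table with a resolved final column); the package computes the interrater
agreement percentage and the disagreement list but never produces labels.

Flattening maps each comment to a directed edge record commenter → author, so
indegree measures attention received. Layer assignment: like/neutral → the
post's layer (weights 2/1); boo (weight 0.2) → the opposing camp. A boo on a
provaccination post deterministically lands in A. A boo on an antivaccination
post is drawn uniformly from {P, H}; a boo on a hesitant post uniformly from
{P, A} — the hesitant case is not forced by any external rule, and the
symmetric extension of the two-way random assignment is the least-assumption
choice. All such draws come from one seeded stream, so flattening is
deterministic.

Design choices worth stating explicitly:

- **Self-comments** (author commenting the own board) are excluded by default
  (configurable): a self-loop would inflate both degree directions of one
  node with no cross-user interaction.
- **Parallel records** between the same (source, target) pair aggregate into
  one edge carrying summed weight, a comment count, and first/last times.
  Degree metrics count distinct neighbors, so aggregation never changes them.
- **Weights** {2, 1, 0.2} are stored but unused by the default metrics, which
  are neighbor counts; weighted variants can be built on the stored edge
  attributes. Negative weights are never produced.
- **Snapshots** are cumulative: a record enters every snapshot at or after
  its timestamp (time ≤ t_n), so V^l and E^l are nondecreasing and the final
  snapshot equals the static network. Time points default to calendar
  month-ends.

## Metrics

Degrees are distinct-neighbor counts per layer and direction; cross-degrees
take the union of neighbor sets over the three layers; layer diversity is the
mean cross-degree over a layer's nodes. Spearman correlations are computed on
the nodes two layers share, with average ranks for ties (scipy); fewer than
two common nodes or a zero-variance degree vector yields NaN with a log
entry — undefined values are always explicit gaps, never silent zeros.

Node entropy uses natural log on p(l)_v = (v's connections in l) / (v's total
connections), where "connections" are distinct in- plus out-neighbors per
layer by default; raw comment counts are selectable. Only orderings and the
0 / ln 3 endpoints matter downstream, and those are base-invariant.

Overlap between two layers defaults to the Jaccard percentage
100·|V^a ∩ V^b| / |V^a ∪ V^b|; the denominator is configurable (min, sum,
or either single layer) because different studies normalize differently.

Hardliners are the k = 30 lowest-entropy nodes per layer among candidates
with at least `min_activity` = 10 total connections; without the floor,
every one-comment user ties at entropy 0 and the selection is meaningless.
Ties break by higher within-layer total degree, then node id. Diverse nodes
are the k = 50 highest by d^M_in + d^M_out, ties by entropy descending then
node id. Hardliner degree reporting standardizes each hardliner's
within-layer degree by the layer's mean degree in the same direction (1.0 =
typical node); the standardization is a documented package choice, as no
canonical scaling exists for this quantity.

## Power-law fitting

The degree-tail fit is a discrete maximum-likelihood estimate of δ in
p(d) ∝ d^−δ, d ≥ x_min, with normalization ζ(δ, x_min) (Hurwitz zeta) and δ
optimized on [1.01, 6] by bounded scalar minimization. x_min is chosen by
minimizing the KS distance between the empirical tail and the fitted model
over candidate values, where a candidate must keep at least 10 points and at
least 5% of the data in its tail — the fraction floor stops x_min from
drifting so far out that any smooth tail looks locally power-law, which would
blunt the goodness-of-fit test. The p-value is a semi-parametric bootstrap
(default 100 replicates): synthetic datasets mix resampled sub-x_min values
with tail draws from the fitted law (inverse-transform sampling via the
continuous approximation x = ⌊(x_min − ½)(1 − u)^(−1/(δ−1)) + ½⌋), are refit
with the full x_min search, and p is the share whose KS distance meets or
exceeds the observed one. Small p rejects the power law. Fits require ≥ 50
nonzero degrees and ≥ 2 distinct values; anything less raises.

Recovery behavior (verified in the test suite): on 5000 draws with true
δ = 2.3 the estimate is within ±0.15 of truth across seeds; geometric
(exponential-tail) samples of the same size are rejected.

## Synthetic forum generator

The generator defines the study conditions for every downstream test. Each
user draws a latent stance with probabilities proportional to 1283:1322:387
(the observed board shares of the three stances), an archetype (hardliner
5%, spanner 5%, background 90%), and an activity level k ~ zeta(α) with
α = 2.3 (the observed degree-tail exponent); the user writes exactly k
comments. Boards are scheduled per layer per month over a 23-month window
starting January 2021, with month index 10 (November 2021, the observed
surge month) receiving 3× posting intensity. Board authors are same-stance
users sampled proportional to activity. Each comment picks a target stance —
hardliners stay home; spanners are uniform over all three; background users
stay home with probability `chambering` (default 0.7, a chambered-but-leaky
forum) and otherwise pick uniformly between the other two stances — then a
concrete board by preferential attachment (∝ 1 + comments received), which
reproduces heavy-tailed indegrees. Reactions are boo with probability 0.10,
neutral 0.30, like otherwise; comment timestamps fall in the board's month at
or after the board. All randomness flows from the config seed through named
streams; identical configs give byte-identical corpora.

What the generator does **not** emulate: comment text content (placeholder
strings), reply-chains between boards, user arrival/churn over time
(stances and activity are fixed for the window), seasonal reaction-mix
shifts, and any coupling between a user's stance and their reaction choice.
Passing tests therefore certify the pipeline's arithmetic and its parameter
sensitivity (entropy and rank divergence respond monotonically to the
chambering probability), not the realism of any particular corpus.

## Bootstrap

The resampling unit is the board with all its comments, drawn with
replacement holding the retained count fixed — the unit at which the human
stance classification (the uncertainty being quantified) operates. Each
replicate reflattens (boo draws reseeded from the root seed), rebuilds the
network, and recomputes the statistic; summaries report the full-data point
estimate, the replicate mean, and the 2.5/97.5 percentile interval,
formatted "mean (low-high)" at two decimals. Replicates where the statistic
is undefined are counted and excluded; a summary with more than half
undefined is flagged. The replicate stream is deterministic given the seed.

A known limitation, measured and documented rather than patched: statistics
defined per *distinct* node or edge (such as the mean degree 2E/V) are
biased under board resampling, because a resample contains on average
1 − 1/e ≈ 63% of distinct boards, thinning distinct-pair and distinct-user
counts by occupancy factors that do not cancel in the ratio. The bias is a
roughly constant fraction of the value regardless of corpus size (≈ −10%
for the default conditions), so percentile CIs for such statistics sit
systematically below the point estimate and under-cover the across-corpus
mean. Statistics linear in boards (e.g. comments per board) are unbiased,
which the test suite uses to verify the machinery itself. For degree-type
statistics the bootstrap intervals should be read as dispersion summaries
of the board-resampling distribution, not as calibrated frequentist
intervals; calibrated alternatives (m-out-of-n or BCa corrections) are out
of scope.

## Problem sizes and numerical conventions

The test suite runs entirely on generated data: toy multilayers of ≤ 12
nodes for brute-force oracle equivalence (100 random instances), 2000-user /
600-board corpora for the chambering-sensitivity grid (chambering ∈ {0.34,
0.6, 0.9}), 5000-sample draws for exponent recovery, 50 small corpora for
serialization round-trips, and 200 corpora of 42 boards × 200 replicates for
bootstrap coverage measurement. Anonymization maps each distinct username to
a distinct 6-character A–Z/0–9 token from a seeded stream (capacity 36^6).
The thread-text dialect wraps comment text at 39 characters per physical
line (continuation lines rejoined on parse) and maps tabs/newlines in free
text to spaces on emit, since they delimit fields. Undefined statistics are
NaN sentinels with log entries throughout.
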