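# Methods

## Setting and data model

A case report is annotated against a taxonomy partitioned into *axes*
(perspectives).  Each axis is a rooted DAG: terms may have several parents
within their axis, never across axes.  Axes are treated as disjoint
partitions with no cross-axis edges even though real perspective schemes
are not fully independent — similarities are computed per axis and then
combined, so a cross-axis term pair simply has no common ancestors and
contributes nothing.  Multiple parents are supported throughout because the
ancestor-based measures (NTO, MICA search) are defined on DAGs and the same
code should run unchanged on deeper ontologies.

## Information content

Annotation frequencies are propagated: a case annotated with term *t*
implicitly instantiates every ancestor of *t*, and each case counts once
per term regardless of how many of its annotations fall below that term.
Then IC(t) = −ln(count(t) / N_axis) in nats, where N_axis is the number of
cases with at least one annotation on that axis.

Two choices here are implementation-defined rather than dictated by the
method:

- **Per-axis probability scope.** The denominator is the axis's annotated
  case count, not the corpus size.  Axes differ in coverage, and since
  similarity is computed per axis before weighting, each axis's IC scale
  should be calibrated to its own annotation density.
- **Zero-count floor.** Terms never observed get
  IC = −ln(1/(2·N_axis)) — half a pseudo-count — instead of +∞.  At a
  few hundred cases the corpus is sparse and many legitimate terms are
  unobserved; the finite floor keeps Lin similarity defined everywhere
  while still ranking unobserved terms as maximally specific.

Both sit behind arguments so a caller can reproduce other conventions.

## The three measures

- **Lin with pairwise averaging.** sim(t₁,t₂) = 2·IC(MICA)/(IC(t₁)+IC(t₂)),
  MICA being the shared ancestor of maximal IC *with the terms themselves
  included* (standard in the Lin literature; required so sim(t,t) = 1).
  Set-level similarity is the mean over all |A|·|B| pairs — the average
  pairwise strategy; MAX/SUM/best-match aggregations are deliberately not
  implemented.  When IC(t₁)+IC(t₂) = 0 (both at probability 1) the pair
  scores 1 if identical, else 0.
- **NTO.** Extended sets A⁺, B⁺ are the unions of reflexive ancestor
  closures, *minus the axis root*: with the root retained every same-axis
  pair would share at least one term and the similarity floor would
  inflate.  The root can be retained via `include_root` for comparison.
  Normalization is by the smaller extended set.
- **VS.** Vectors span one axis's term universe (per-axis vectors, not a
  concatenation over all axes — consistent with per-axis combination and
  with single-axis filtering).  Default is binary entries over the direct
  annotations; `frequency` mode substitutes IC values, i.e. an
  inverse-document-frequency weighting, and `vs_extend_ancestors` optionally
  extends the sets by their ancestors first.

Empty-set convention: one side empty scores 0 (one-sided absence cannot
support similarity); both sides empty excludes the axis and renormalizes
the remaining weights (absence of annotation is missing data, not evidence
of dissimilarity).  The overall score is a convex combination, so it stays
in [0,1] without clipping.  Rankings break score ties by case id ascending,
making every output deterministic.

## Evaluation protocol

The review list for a query takes `n_nonzero` = 15 cases representing the
nonzero-score distribution plus `n_zero` = 5 uniformly drawn zero-score
cases (so roughly a quarter of the list is irrelevant by construction).
"Representing the distribution" is implemented as stratified
equal-frequency sampling: the nonzero entries are split in rank order into
15 strata and one case is drawn per stratum; a `top` mode takes the head of
the ranking instead.  Both modes are deterministic under a seed.

Algorithm scores become Likert labels by distribution matching: cases are
sorted ascending by score (ties by case id) and the experts' label counts
(c₁,c₂,c₃,c₄) are assigned lowest-first.  Agreement binarizes both
labelings into {1,2} vs {3,4} and counts matching sides.  The null
distribution permutes the expert label *multiset* over the cases (10,000
replicates by default; a uniform-over-{1..4} mode exists behind a flag but
does not preserve the label mix).  The t-test follows the protocol
literally: the baseline sample is tested against the observed ratio as the
hypothesized mean, two-sided, df = replicates − 1.  Testing the fixed
quantity as the hypothesized mean of the random sample is statistically
unusual (the standard error shrinks with replicates, so p-values are
extreme whenever the ratio differs from the null mean at all); a direct
permutation p-value — the fraction of baseline replicates at or above the
observed ratio — is therefore reported alongside.  Stars follow the usual
convention (** p < 0.01, * 0.01 ≤ p < 0.05).  Multi-expert input is
assessed per expert; a majority-vote utility builds consensus labels, ties
resolved toward the higher label (conservative toward relevance).

## Feedback weight updates

The feedback contract only fixes *that* user verdicts tune the axis
weights; the rule here is a Hedge-style multiplicative update chosen for
its guarantees: w_a ← w_a·exp(η·y·(sim_a − overall)), y = ±1, then
renormalize.  Weights stay strictly positive and on the simplex, so no
sequence of verdicts can irreversibly zero an axis.  Because the
(−overall) term is constant across axes within one event, it cancels under
renormalization when every axis is scored; its role is to keep axes that
were skipped (both cases unannotated) neutral.  Consequently, after n
events the log-weights concentrate like η·Σ y·sim_a: the product η·n sets
how sharply the weight vector peaks.  The API default η = 0.1 suits
long-running incremental use; the weight-recovery experiment (200 events in
one batch) uses η = 0.03, at which the learned vector lands near the
interior ground truth rather than overshooting onto the single
highest-gap axis.  Feedback is persisted as an append-only JSON Lines log
and replayed in timestamp order, so final weights are a pure function of
(initial weights, log).

## Synthetic data generator

No machine-readable PSE taxonomy or annotated corpus is publicly
deposited, so the generator emulates the documented scale: 6 axes, 219
terms, 366 cases.  Defaults (frozen as the study conditions):

| parameter | default | meaning |
|---|---|---|
| `max_depth` | 4 | levels per axis; perspective schemes are shallow |
| `branching` | 3.0 | child cap for interior nodes |
| `root_fanout` | 8 | child cap at the root — broad top-level categories |
| `second_parent_prob` | 0.08 | chance of a second parent (true DAG) |
| `n_clusters` | 6 | planted event themes |
| `theme_prob` | 0.8 | annotation drawn from the case's theme subtree |
| `annotations_per_axis` | 1–3 | direct annotations per axis per case |
| `background_zipf_exponent` | 1.3 | skew of background term usage |
| `rating_noise` | 0.1 | chance a simulated expert label is resampled |

Cluster themes are *subtrees* (one depth-1 anchor per axis per cluster),
not arbitrary term sets, so ancestor-based measures have signal by
construction.  A theme keeps only the anchor subtree's exclusive terms:
multi-parent terms bridging two depth-1 subtrees are dropped, so two
clusters' themes overlap exactly when they share an anchor (possible only
when clusters outnumber top-level branches) rather than through one
incidental bridge term.  Background draws are Zipf-weighted so IC values
spread realistically.  Simulated experts rate same-cluster cases 4,
overlapping-theme clusters 3, others 1 or 2, with `rating_noise`
resampling.  Simulated feedback pairs are rejection-sampled to nonzero
similarity — feedback is only ever given on retrieved cases — and the
simulated user agrees when the truth-weighted overall similarity exceeds
the sampled median, so verdicts depend on *which* axes match.

What the generator does not emulate: real per-category term frequencies,
annotation quality drift between reporters, correlated axes, and free-text
narratives.  Passing tests therefore demonstrate that the machinery
recovers structure that is genuinely present at realistic scale and
sparsity; they do not certify retrieval quality on any real reporting
system's data.

## Problem sizes and numerics

The test suite runs the full-scale configuration (366 cases) for
end-to-end checks and 10–60-case corpora for oracle comparisons; oracle
equivalence is asserted to 1e−12 against brute-force reimplementations.
The pairwise average uses compensated summation (`math.fsum`) so set
similarity is exactly symmetric under argument swap; the VS cosine is
clamped at 1 against floating-point drift.  Permutation baselines use
10,000 replicates as in the protocol; enumeration cross-checks use ≤ 5!
permutations.  All generators and samplers are pure functions of
(config, seed), with independent substreams per artifact so regenerating
one does not disturb another.

## Known limitations

- Expert-agreement results on synthetic data inherit the generator's
  idealizations (disjoint themes, noise-free cluster truth behind the
  labels); real expert panels disagree more structurally.
- The t-test direction is kept for fidelity to the protocol despite its
  statistical oddity; use the reported permutation p-value for inference.
- Only the six axis weights are learned from feedback; per-term or
  per-measure weighting is out of scope, as are edge-based (path-count)
  similarity measures and best-pair aggregation.
- No NLP over case narratives; free text is carried opaquely.
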