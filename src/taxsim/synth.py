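"""Synthetic taxonomies, corpora and expert ratings.

No machine-readable patient-safety taxonomy or annotated case corpus is
publicly deposited, so every other module is exercised on generated data
that emulates the real setting's scale: six axes totalling 219 terms, and
366 annotated case reports.

The corpus carries *planted cluster structure*: each case belongs to one of
``n_clusters`` event themes (e.g. "nosocomial infection"), each theme owns
one subtree per axis, and each annotation is drawn from the case's theme
subtree with probability ``theme_prob``, otherwise from a Zipf-weighted
background over the whole axis.  Themes are subtrees rather than arbitrary
term sets so ancestor-based measures (term overlap, common-ancestor IC)
have signal by construction.  Simulated expert ratings are a noisy readout
of the cluster truth, which gives an end-to-end gold standard without any
human in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .assessment import GoldStandard
from .corpus import CaseReport, Corpus, ICTable
from .errors import TaxsimError
from .feedback import FeedbackRecord, combine_with_weights
from .similarity import AxisWeights, MeasureConfig, axis_combined_similarity
from .taxonomy import Taxonomy, Term

__all__ = [
    "SynthConfig",
    "ClusterTruth",
    "DEFAULT_AXES",
    "generate_taxonomy",
    "generate_corpus",
    "generate_expert_ratings",
    "simulate_feedback",
]

# plausible perspective names for a patient-safety taxonomy
DEFAULT_AXES = (
    "safety_target",
    "error_type",
    "approach",
    "clinical_area",
    "setting",
    "target_audience",
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; the defaults emulate the real corpus scale
    (six axes, 219 terms, 366 cases)."""

    n_axes: int = 6
    n_terms: int = 219
    max_depth: int = 4
    branching: float = 3.0
    root_fanout: int = 8
    second_parent_prob: float = 0.08
    n_cases: int = 366
    n_clusters: int = 6
    theme_prob: float = 0.8
    annotations_per_axis: tuple[int, int] = (1, 3)
    background_zipf_exponent: float = 1.3
    rating_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axes < 1 or self.n_terms < 1 or self.n_cases < 1:
            raise TaxsimError("counts must be positive")
        if self.n_terms < self.n_axes:
            raise TaxsimError("need at least one term per axis")
        if not (0.0 <= self.theme_prob <= 1.0 and 0.0 <= self.rating_noise <= 1.0):
            raise TaxsimError("probabilities must lie in [0, 1]")
        lo, hi = self.annotations_per_axis
        if lo < 1 or hi < lo:
            raise TaxsimError("annotations_per_axis must be a positive range")


@dataclass(frozen=True)
class ClusterTruth:
    """Planted structure behind a generated corpus."""

    assignment: Mapping[str, int]
    theme_terms: Mapping[tuple[int, str], frozenset[str]]

    def overlapping(self, c1: int, c2: int) -> bool:
        """Whether two clusters' themes share any term on any axis."""
        axes = {a for (c, a) in self.theme_terms if c == c1}
        return any(
            self.theme_terms.get((c1, a), frozenset())
            & self.theme_terms.get((c2, a), frozenset())
            for a in axes
        )


def _axis_rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent substreams so e.g. regenerating ratings does not disturb
    # the corpus draw
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def generate_taxonomy(config: SynthConfig = SynthConfig()) -> Taxonomy:
    """Random multi-axis taxonomy: one rooted DAG per axis.

    Terms are attached one at a time to a parent drawn among terms whose
    depth is below ``max_depth`` and whose child count is below
    ``branching``; with ``branching <= 1`` each axis degenerates to a chain.
    A small fraction of terms receives a second parent, so the result is a
    genuine DAG rather than a forest of trees.
    """
    rng = _axis_rng(config, 1)
    axis_names = [
        DEFAULT_AXES[i] if i < len(DEFAULT_AXES) else f"axis_{i + 1}"
        for i in range(config.n_axes)
    ]
    # spread terms as evenly as the total allows
    base, extra = divmod(config.n_terms, config.n_axes)
    sizes = [base + (1 if i < extra else 0) for i in range(config.n_axes)]
    terms: list[Term] = []
    for axis_id, size in zip(axis_names, sizes):
        ids = [f"{axis_id}:{k:03d}" for k in range(size)]
        depth = {ids[0]: 0}
        children: dict[str, int] = {ids[0]: 0}
        parents: dict[str, set[str]] = {ids[0]: set()}
        for k in range(1, size):
            tid = ids[k]
            existing = ids[:k]
            if config.branching <= 1.0:
                parent = existing[-1]  # chain
            else:
                cap = max(1, round(config.branching))
                # the root fans out wider than interior nodes, mirroring the
                # broad top-level categories of real classification schemes
                open_slots = [
                    t
                    for t in existing
                    if depth[t] < config.max_depth - 1
                    and children[t] < (config.root_fanout if depth[t] == 0 else cap)
                ]
                candidates = open_slots or [
                    t for t in existing if depth[t] < config.max_depth - 1
                ] or existing
                parent = candidates[int(rng.integers(len(candidates)))]
            parents[tid] = {parent}
            children[parent] = children.get(parent, 0) + 1
            children[tid] = 0
            depth[tid] = depth[parent] + 1
            if (
                k >= 2
                and config.branching > 1.0
                and rng.random() < config.second_parent_prob
            ):
                others = [
                    t
                    for t in existing
                    if t != parent and depth[t] < config.max_depth - 1
                ]
                if others:
                    second = others[int(rng.integers(len(others)))]
                    parents[tid].add(second)
                    children[second] = children.get(second, 0) + 1
        for tid in ids:
            terms.append(
                Term(tid, f"{axis_id} term {tid.split(':')[1]}", axis_id,
                     frozenset(parents[tid]))
            )
    return Taxonomy(terms)


def _zipf_weights(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    ranks = rng.permutation(n) + 1
    w = 1.0 / ranks.astype(float) ** exponent
    return w / w.sum()


def generate_corpus(
    taxonomy: Taxonomy, config: SynthConfig = SynthConfig()
) -> tuple[Corpus, ClusterTruth]:
    """Annotated corpus with planted clusters.

    Cases are assigned to clusters round-robin.  Each cluster owns, per
    axis, a theme subtree rooted at a random depth-1 term; each of the
    case's annotation draws comes from that subtree with probability
    ``theme_prob`` and from the Zipf background otherwise.
    """
    rng = _axis_rng(config, 2)
    axis_ids = sorted(taxonomy.axes)
    non_root: dict[str, list[str]] = {}
    depth1: dict[str, list[str]] = {}
    for axis_id in axis_ids:
        axis = taxonomy.axes[axis_id]
        members = sorted(axis.term_ids - {axis.root_id})
        non_root[axis_id] = members
        depth1[axis_id] = [
            t for t in members if axis.root_id in taxonomy[t].parent_ids
        ] or members
    themes: dict[tuple[int, str], frozenset[str]] = {}
    # A theme is the *exclusive* part of a depth-1 subtree: multi-parent
    # terms bridging two subtrees are dropped, so distinct anchors give
    # disjoint themes and theme overlap means two clusters genuinely share
    # an anchor (only possible when clusters outnumber top-level branches).
    for axis_id in axis_ids:
        anchors = depth1[axis_id]
        subtrees = {a: taxonomy.descendants(a, include_self=True) for a in anchors}
        membership: dict[str, int] = {}
        for sub in subtrees.values():
            for t in sub:
                membership[t] = membership.get(t, 0) + 1
        exclusive = {
            a: frozenset(t for t in sub if membership[t] == 1) or frozenset(sub)
            for a, sub in subtrees.items()
        }
        order = [anchors[i] for i in rng.permutation(len(anchors))]
        for cluster in range(config.n_clusters):
            theme = exclusive[order[cluster % len(order)]]
            if not theme:
                raise TaxsimError(f"empty theme subtree for axis {axis_id!r}")
            themes[(cluster, axis_id)] = theme
    background = {
        axis_id: _zipf_weights(
            len(non_root[axis_id]), config.background_zipf_exponent, rng
        )
        for axis_id in axis_ids
    }
    lo, hi = config.annotations_per_axis
    width = len(str(config.n_cases))
    cases: list[CaseReport] = []
    assignment: dict[str, int] = {}
    for i in range(config.n_cases):
        case_id = f"case_{i + 1:0{width}d}"
        cluster = i % config.n_clusters
        assignment[case_id] = cluster
        annotations: dict[str, frozenset[str]] = {}
        for axis_id in axis_ids:
            theme = sorted(themes[(cluster, axis_id)])
            pool = non_root[axis_id]
            k = int(rng.integers(lo, hi + 1))
            drawn: set[str] = set()
            for _ in range(k):
                if rng.random() < config.theme_prob:
                    drawn.add(theme[int(rng.integers(len(theme)))])
                else:
                    drawn.add(
                        pool[int(rng.choice(len(pool), p=background[axis_id]))]
                    )
            annotations[axis_id] = frozenset(drawn)
        cases.append(CaseReport(case_id, annotations))
    return Corpus(cases), ClusterTruth(assignment=assignment, theme_terms=themes)


def generate_expert_ratings(
    truth: ClusterTruth,
    query: str,
    review_list: list[str],
    config: SynthConfig = SynthConfig(),
) -> GoldStandard:
    """Simulated consensus Likert labels for a review list.

    Same-cluster cases rate 4 (highly relevant); cases from a cluster whose
    themes overlap the query's rate 3; all others rate 1 or 2 uniformly.
    Each label is independently resampled uniformly from {1..4} with
    probability ``rating_noise``.
    """
    if query not in truth.assignment:
        raise TaxsimError(f"query {query!r} missing from cluster truth")
    rng = _axis_rng(config, 3)
    q_cluster = truth.assignment[query]
    labels: dict[str, int] = {}
    for case_id in review_list:
        if case_id not in truth.assignment:
            raise TaxsimError(f"review case {case_id!r} missing from cluster truth")
        cluster = truth.assignment[case_id]
        if cluster == q_cluster:
            label = 4
        elif truth.overlapping(q_cluster, cluster):
            label = 3
        else:
            label = int(rng.integers(1, 3))
        if rng.random() < config.rating_noise:
            label = int(rng.integers(1, 5))
        labels[case_id] = label
    return GoldStandard(query_id=query, labels=labels)


def simulate_feedback(
    corpus: Corpus,
    ic: ICTable,
    taxonomy: Taxonomy,
    truth_weights: AxisWeights,
    config: MeasureConfig = MeasureConfig(),
    n_events: int = 200,
    seed: int = 0,
) -> list[tuple[FeedbackRecord, Mapping[str, float]]]:
    """Simulate agree/disagree feedback from a ground-truth weight vector.

    Feedback is only ever given on *retrieved* cases, so candidate (query,
    case) pairs are rejection-sampled until they show nonzero similarity on
    at least one axis.  A user who weighs the axes by ``truth_weights``
    agrees with a retrieved case iff its truth-weighted overall similarity
    exceeds the median over the sampled pairs (so both verdicts occur and
    the verdict depends on *which* axes match, not whether any does).
    Returns (record, per-axis scores) events ready for
    :func:`taxsim.feedback.apply_feedback_events`.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 4])
    case_ids = sorted(corpus.cases)
    if len(case_ids) < 2:
        raise TaxsimError("need at least two cases to simulate feedback")
    pairs: list[tuple[str, str, dict[str, float]]] = []
    truth_scores: list[float] = []
    attempts = 0
    max_attempts = 200 * n_events
    while len(pairs) < n_events:
        attempts += 1
        if attempts > max_attempts:
            raise TaxsimError(
                "could not find enough nonzero-similarity pairs; corpus too sparse"
            )
        qi, ci = rng.choice(len(case_ids), size=2, replace=False)
        q, c = case_ids[int(qi)], case_ids[int(ci)]
        _, per_axis = axis_combined_similarity(
            corpus[q], corpus[c], truth_weights, config, ic, taxonomy
        )
        if not any(s > 0.0 for s in per_axis.values()):
            continue
        pairs.append((q, c, per_axis))
        truth_scores.append(combine_with_weights(truth_weights, per_axis))
    threshold = float(np.median(truth_scores))
    events = []
    for (q, c, per_axis), score in zip(pairs, truth_scores):
        verdict = "agree" if score > threshold else "disagree"
        events.append((FeedbackRecord(q, c, verdict), per_axis))
    return events
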