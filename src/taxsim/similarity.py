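"""The three semantic similarity measures, axis combination and retrieval.

Term-level similarity follows Lin: for terms t1, t2 with information
contents IC(t1), IC(t2) and most informative common ancestor (MICA, the
shared ancestor of highest IC, the terms themselves included),

    sim_Lin(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2)).

Set-level measures on two same-axis annotation sets A, B:

``ic`` (pairwise average)
    mean of sim_Lin over all |A| x |B| term pairs.
``nto`` (normalized term overlap)
    |A+ & B+| / min(|A+|, |B+|) where A+ is A extended with all ancestors,
    axis root excluded (every same-axis pair would otherwise share it and
    the floor similarity would inflate).
``vs`` (vector space)
    cosine of annotation vectors over the axis's term universe; binary by
    default, or with IC values replacing the ones (inverse-frequency
    weighting) in ``frequency`` mode.

Case-level similarity is the convex combination of per-axis scores under a
normalized weight vector.  Axes where *both* cases are unannotated carry no
evidence and are excluded (remaining weights renormalized); axes where
exactly one case is unannotated score 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import CaseReport, Corpus, ICTable
from .errors import CorpusError, CrossAxisError, TaxsimError
from .taxonomy import Taxonomy

__all__ = [
    "AxisWeights",
    "MeasureConfig",
    "RankedResult",
    "lin_similarity",
    "pairwise_average_similarity",
    "nto_similarity",
    "vs_similarity",
    "axis_combined_similarity",
    "rank_similar_cases",
]

MEASURES = ("ic", "nto", "vs")


@dataclass(frozen=True)
class AxisWeights:
    """Normalized non-negative combination weights, one per axis."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise TaxsimError("AxisWeights needs at least one axis")
        if any(w < 0 for w in self.weights.values()):
            raise TaxsimError("axis weights must be non-negative")
        total = sum(self.weights.values())
        if total <= 0:
            raise TaxsimError("at least one axis weight must be positive")
        object.__setattr__(
            self, "weights", {a: w / total for a, w in self.weights.items()}
        )

    @classmethod
    def equal(cls, axis_ids: Iterable[str]) -> "AxisWeights":
        """Equal weights over the given axes — the default starting point."""
        ids = list(axis_ids)
        return cls({a: 1.0 / len(ids) for a in ids})

    def __getitem__(self, axis_id: str) -> float:
        return self.weights[axis_id]

    def restricted(self, axis_ids: Iterable[str]) -> "AxisWeights":
        """Renormalized weights over a subset of axes."""
        sub = {a: self.weights[a] for a in axis_ids}
        return AxisWeights(sub)


@dataclass(frozen=True)
class MeasureConfig:
    """Which measure to run and its knobs.

    ``vs_weighting`` and ``vs_extend_ancestors`` are ignored unless
    ``measure == "vs"``; ``nto_include_root`` is ignored unless
    ``measure == "nto"``.  Pairwise aggregation is fixed to the average.
    """

    measure: str = "vs"
    vs_weighting: str = "binary"  # or "frequency"
    vs_extend_ancestors: bool = False
    nto_include_root: bool = False
    pairwise_aggregation: str = "average"

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise TaxsimError(f"unknown measure {self.measure!r}; expected {MEASURES}")
        if self.vs_weighting not in ("binary", "frequency"):
            raise TaxsimError(f"unknown vs_weighting {self.vs_weighting!r}")
        if self.pairwise_aggregation != "average":
            raise TaxsimError("only average pairwise aggregation is supported")


@dataclass(frozen=True)
class RankedResult:
    """Ranked retrieval output for one query case.

    ``entries`` is sorted by similarity descending, ties broken by case id
    ascending; the query itself is excluded.  ``per_axis`` maps
    ``(case_id, axis_id)`` to the axis-level similarity.
    """

    query_id: str
    entries: tuple[tuple[str, float], ...]
    per_axis: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def scores(self) -> dict[str, float]:
        return dict(self.entries)

    def nonzero(self) -> list[tuple[str, float]]:
        return [(c, s) for c, s in self.entries if s > 0.0]

    def zero(self) -> list[tuple[str, float]]:
        return [(c, s) for c, s in self.entries if s == 0.0]


# -- term-level ---------------------------------------------------------------


def lin_similarity(ic: ICTable, taxonomy: Taxonomy, t1: str, t2: str) -> float:
    """Lin similarity of two terms; 0 across axes, in [0, 1] always."""
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    cached = ic._lin_cache.get(key)
    if cached is not None:
        return cached
    common = taxonomy.common_ancestors(t1, t2)
    if not common:
        sim = 0.0
    else:
        denom = ic.ic[t1] + ic.ic[t2]
        if denom == 0.0:
            sim = 1.0 if t1 == t2 else 0.0
        else:
            mica_ic = max(ic.ic[a] for a in common)
            sim = 2.0 * mica_ic / denom
    ic._lin_cache[key] = sim
    return sim


# -- set-level ----------------------------------------------------------------


def _axis_of_sets(taxonomy: Taxonomy, *sets: frozenset[str]) -> str | None:
    axes = {taxonomy.axis_of(t) for s in sets for t in s}
    if len(axes) > 1:
        raise CrossAxisError(f"annotation sets span axes {sorted(axes)}")
    return next(iter(axes)) if axes else None


def pairwise_average_similarity(
    ic: ICTable, taxonomy: Taxonomy, A: frozenset[str], B: frozenset[str]
) -> float:
    """Mean Lin similarity over all term pairs of two same-axis sets.

    Either side empty gives 0: one-sided absence of annotation cannot
    support similarity.
    """
    _axis_of_sets(taxonomy, A, B)
    if not A or not B:
        return 0.0
    # fsum is order-independent, keeping sim(A, B) == sim(B, A) exactly
    total = math.fsum(lin_similarity(ic, taxonomy, a, b) for a in A for b in B)
    return total / (len(A) * len(B))


def nto_similarity(
    taxonomy: Taxonomy,
    A: frozenset[str],
    B: frozenset[str],
    include_root: bool = False,
) -> float:
    """Normalized overlap of ancestor-extended annotation sets."""
    axis = _axis_of_sets(taxonomy, A, B)
    if not A or not B:
        return 0.0
    root = taxonomy.axes[axis].root_id
    a_ext: set[str] = set()
    for t in A:
        a_ext |= taxonomy.ancestors(t, include_self=True)
    b_ext: set[str] = set()
    for t in B:
        b_ext |= taxonomy.ancestors(t, include_self=True)
    if not include_root:
        a_ext.discard(root)
        b_ext.discard(root)
    if not a_ext or not b_ext:
        return 0.0
    return len(a_ext & b_ext) / min(len(a_ext), len(b_ext))


def vs_similarity(
    taxonomy: Taxonomy,
    ic: ICTable | None,
    A: frozenset[str],
    B: frozenset[str],
    config: MeasureConfig = MeasureConfig(measure="vs"),
) -> float:
    """Cosine similarity of annotation vectors over the axis term universe."""
    axis = _axis_of_sets(taxonomy, A, B)
    if not A or not B:
        return 0.0
    if config.vs_weighting == "frequency" and ic is None:
        raise TaxsimError("frequency-weighted VS requires an ICTable")
    if config.vs_extend_ancestors:
        A = frozenset().union(*(taxonomy.ancestors(t, include_self=True) for t in A))
        B = frozenset().union(*(taxonomy.ancestors(t, include_self=True) for t in B))
    universe = sorted(taxonomy.axes[axis].term_ids)
    index = {t: i for i, t in enumerate(universe)}

    def vector(terms: frozenset[str]) -> np.ndarray:
        v = np.zeros(len(universe))
        for t in terms:
            v[index[t]] = ic.ic[t] if config.vs_weighting == "frequency" else 1.0
        return v

    va, vb = vector(A), vector(B)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    # guard against cosine drifting to 1 + eps in floating point
    return float(min(1.0, np.dot(va, vb) / (na * nb)))


def _axis_similarity(
    A: frozenset[str],
    B: frozenset[str],
    config: MeasureConfig,
    ic: ICTable,
    taxonomy: Taxonomy,
) -> float:
    if config.measure == "ic":
        return pairwise_average_similarity(ic, taxonomy, A, B)
    if config.measure == "nto":
        return nto_similarity(taxonomy, A, B, include_root=config.nto_include_root)
    return vs_similarity(taxonomy, ic, A, B, config)


# -- case-level ---------------------------------------------------------------


def axis_combined_similarity(
    case1: CaseReport,
    case2: CaseReport,
    weights: AxisWeights,
    config: MeasureConfig,
    ic: ICTable,
    taxonomy: Taxonomy,
    axis_filter: Iterable[str] | None = None,
) -> tuple[float, dict[str, float]]:
    """Weighted per-axis similarity of two cases.

    Returns ``(overall, per_axis)``.  Axes where both cases are unannotated
    are excluded and the remaining weights renormalized; if every considered
    axis is empty on both sides the overall score is 0.
    """
    if axis_filter is None:
        axes = list(weights.weights)
    else:
        axes = list(axis_filter)
        unknown = [a for a in axes if a not in weights.weights]
        if unknown:
            raise TaxsimError(f"axis filter names unknown axes {unknown}")
    empty: frozenset[str] = frozenset()
    per_axis: dict[str, float] = {}
    active: list[str] = []
    for axis_id in axes:
        A = case1.annotations.get(axis_id, empty)
        B = case2.annotations.get(axis_id, empty)
        if not A and not B:
            continue
        per_axis[axis_id] = _axis_similarity(A, B, config, ic, taxonomy)
        active.append(axis_id)
    if not active:
        return 0.0, per_axis
    w = weights.restricted(active)
    overall = sum(w[a] * per_axis[a] for a in active)
    return overall, per_axis


def rank_similar_cases(
    corpus: Corpus,
    query: str,
    weights: AxisWeights,
    config: MeasureConfig,
    ic: ICTable,
    taxonomy: Taxonomy,
    axis_filter: Sequence[str] | None = None,
) -> RankedResult:
    """Score every non-query case against the query and rank descending.

    Ties are broken by case id ascending so the ranking is deterministic.
    ``axis_filter`` restricts both the computation and the weight
    renormalization to the named axes.
    """
    query_case = corpus[query]
    if axis_filter is not None:
        unknown = [a for a in axis_filter if a not in taxonomy.axes]
        if unknown:
            raise TaxsimError(f"axis filter names unknown axes {unknown}")
    scored: list[tuple[str, float]] = []
    per_axis: dict[tuple[str, str], float] = {}
    for case_id, case in corpus.cases.items():
        if case_id == query:
            continue
        overall, axis_scores = axis_combined_similarity(
            query_case, case, weights, config, ic, taxonomy, axis_filter
        )
        scored.append((case_id, overall))
        for axis_id, s in axis_scores.items():
            per_axis[(case_id, axis_id)] = s
    scored.sort(key=lambda e: (-e[1], e[0]))
    return RankedResult(query_id=query, entries=tuple(scored), per_axis=per_axis)
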