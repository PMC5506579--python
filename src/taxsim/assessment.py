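"""Expert-review assessment: review lists, label matching, agreement, baseline.

The evaluation protocol compares a similarity ranking against expert
judgements on a 4-point Likert scale (1 irrelevant, 2 somewhat irrelevant,
3 relevant, 4 highly relevant):

1.  A *review list* is sampled from the ranking: a fixed number of
    nonzero-score cases chosen to represent the nonzero score distribution,
    plus a handful of zero-score cases so roughly a quarter of the list is
    irrelevant by construction.
2.  Experts label the list; the consensus is the gold standard.
3.  The algorithm's scores are converted to Likert labels by *distribution
    matching*: the label histogram is forced to equal the experts', lowest
    scores receiving the lowest labels.
4.  The *agreement ratio* is the fraction of cases whose binarized side
    ({1,2} vs {3,4}) matches between expert and algorithm.
5.  A permutation baseline reassigns the expert label multiset uniformly at
    random many times; a one-sample t-test asks whether the observed ratio
    sits outside that null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDistributionError, TaxsimError
from .similarity import RankedResult

__all__ = [
    "GoldStandard",
    "AgreementResult",
    "sample_review_list",
    "distribution_matched_labels",
    "agreement_ratio",
    "random_baseline",
    "one_sample_t_test",
    "permutation_pvalue",
    "significance_stars",
    "majority_vote",
    "assess_agreement",
]

logger = logging.getLogger(__name__)

LIKERT_VALUES = (1, 2, 3, 4)


def _check_label(value: int) -> int:
    if value not in LIKERT_VALUES:
        raise TaxsimError(f"Likert label must be in {LIKERT_VALUES}, got {value!r}")
    return int(value)


def _relevant(value: int) -> bool:
    """Binarize a Likert label: {3, 4} is the relevant side."""
    return value >= 3


@dataclass(frozen=True)
class GoldStandard:
    """Consensus expert labels for one query's review list."""

    query_id: str
    labels: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.query_id in self.labels:
            raise TaxsimError("query case must not appear in its own gold standard")
        for v in self.labels.values():
            _check_label(v)

    def label_counts(self) -> tuple[int, int, int, int]:
        values = list(self.labels.values())
        return tuple(values.count(v) for v in LIKERT_VALUES)  # type: ignore[return-value]


@dataclass(frozen=True)
class AgreementResult:
    """Observed agreement ratio against its permutation baseline."""

    sample_ratio: float
    baseline_ratios: tuple[float, ...]
    baseline_mean: float
    t_statistic: float
    p_value: float
    permutation_p: float
    replicates: int
    stars: str = ""


def sample_review_list(
    ranked: RankedResult,
    n_nonzero: int = 15,
    n_zero: int = 5,
    seed: int = 0,
    mode: str = "stratified",
) -> list[str]:
    """Draw a review list from a ranking: nonzero-score representatives
    plus random zero-score cases.

    ``stratified`` mode splits the nonzero entries (in rank order) into
    ``n_nonzero`` equal-frequency strata and draws one case per stratum, so
    the list spans the whole nonzero score distribution; ``top`` mode simply
    takes the ``n_nonzero`` highest-ranked cases.  If fewer cases than
    requested exist on either side, all available are taken with a warning.
    """
    if mode not in ("stratified", "top"):
        raise TaxsimError(f"unknown sampling mode {mode!r}")
    nonzero = ranked.nonzero()
    zero = ranked.zero()
    if not nonzero:
        raise TaxsimError(f"query {ranked.query_id!r} has no nonzero-score cases")
    rng = np.random.default_rng(seed)
    if len(nonzero) <= n_nonzero:
        if len(nonzero) < n_nonzero:
            logger.warning(
                "only %d nonzero-score cases available (%d requested)",
                len(nonzero), n_nonzero,
            )
        picked = [c for c, _ in nonzero]
    elif mode == "top":
        picked = [c for c, _ in nonzero[:n_nonzero]]
    else:
        strata = np.array_split(np.arange(len(nonzero)), n_nonzero)
        picked = [nonzero[int(rng.choice(s))][0] for s in strata]
    n_zero_take = min(n_zero, len(zero))
    if n_zero_take < n_zero:
        logger.warning(
            "only %d zero-score cases available (%d requested)", len(zero), n_zero
        )
    zero_ids = [c for c, _ in zero]
    zero_picked = (
        [zero_ids[i] for i in rng.choice(len(zero_ids), n_zero_take, replace=False)]
        if n_zero_take
        else []
    )
    return picked + zero_picked


def distribution_matched_labels(
    scores: Mapping[str, float], counts: Sequence[int]
) -> dict[str, int]:
    """Assign Likert labels to scored cases so the label histogram equals
    ``counts`` = (c1, c2, c3, c4), lowest scores getting the lowest labels.

    Ties in score are broken by case id ascending.
    """
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise TaxsimError("counts must be four non-negative integers")
    if sum(counts) != len(scores):
        raise TaxsimError(
            f"label counts sum to {sum(counts)} but {len(scores)} cases are scored"
        )
    ordered = sorted(scores, key=lambda c: (scores[c], c))
    labels: dict[str, int] = {}
    pos = 0
    for label, count in zip(LIKERT_VALUES, counts):
        for case_id in ordered[pos : pos + count]:
            labels[case_id] = label
        pos += count
    return labels


def agreement_ratio(
    expert: Mapping[str, int], algo: Mapping[str, int]
) -> float:
    """Fraction of cases whose binarized Likert side matches."""
    if not expert:
        raise TaxsimError("cannot compute agreement over an empty labeling")
    if set(expert) != set(algo):
        raise TaxsimError("expert and algorithm labelings cover different cases")
    matches = sum(
        _relevant(_check_label(expert[c])) == _relevant(_check_label(algo[c]))
        for c in expert
    )
    return matches / len(expert)


def random_baseline(
    expert: Mapping[str, int],
    replicates: int = 10_000,
    seed: int = 0,
    mode: str = "permute",
) -> list[float]:
    """Null distribution of agreement ratios under random labeling.

    ``permute`` (default) reassigns the expert label *multiset* to the cases
    uniformly at random, preserving the label distribution; ``uniform``
    draws each label independently from {1..4}.
    """
    if replicates < 1:
        raise TaxsimError("replicates must be positive")
    if mode not in ("permute", "uniform"):
        raise TaxsimError(f"unknown baseline mode {mode!r}")
    if not expert:
        raise TaxsimError("expert labeling is empty")
    rng = np.random.default_rng(seed)
    sides = np.array([_relevant(_check_label(v)) for v in expert.values()])
    m = sides.size
    if mode == "permute":
        ratios = [
            float(np.mean(rng.permutation(sides) == sides)) for _ in range(replicates)
        ]
    else:
        draws = rng.integers(1, 5, size=(replicates, m)) >= 3
        ratios = [float(np.mean(row == sides)) for row in draws]
    return ratios


def one_sample_t_test(
    baseline: Sequence[float], observed: float
) -> tuple[float, float]:
    """One-sample t-test of the baseline mean against the observed ratio.

    Tests the baseline sample against the observed value as hypothesized
    mean: t = (mean(baseline) - observed) / (sd / sqrt(n)), two-sided p on
    n - 1 degrees of freedom.  A strongly negative t means the observed
    ratio sits far above the null.
    """
    x = np.asarray(baseline, dtype=float)
    n = x.size
    if n < 2:
        raise TaxsimError("baseline needs at least two replicates")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDistributionError(
            "baseline has zero variance; observed ratio lies outside any "
            "t-distribution support"
        )
    t = (x.mean() - observed) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def permutation_pvalue(baseline: Sequence[float], observed: float) -> float:
    """Fraction of baseline replicates at or above the observed ratio —
    the direct one-sided permutation p-value companion to the t-test."""
    x = np.asarray(baseline, dtype=float)
    if x.size == 0:
        raise TaxsimError("baseline is empty")
    return float(np.mean(x >= observed))


def significance_stars(p: float) -> str:
    """Two-star convention: ``**`` for p < 0.01, ``*`` for 0.01 <= p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def majority_vote(per_expert: Mapping[str, Mapping[str, int]]) -> dict[str, int]:
    """Consensus labels by majority over experts; ties take the higher label
    (conservative toward relevance) with a logged notice."""
    if not per_expert:
        raise TaxsimError("no expert labelings supplied")
    case_ids = set().union(*(set(lbls) for lbls in per_expert.values()))
    consensus: dict[str, int] = {}
    for case_id in case_ids:
        votes = [
            _check_label(lbls[case_id])
            for lbls in per_expert.values()
            if case_id in lbls
        ]
        counts = {v: votes.count(v) for v in set(votes)}
        best = max(counts.values())
        winners = sorted(v for v, c in counts.items() if c == best)
        if len(winners) > 1:
            logger.info(
                "case %s: tie among labels %s, taking %d", case_id, winners, winners[-1]
            )
        consensus[case_id] = winners[-1]
    return consensus


def assess_agreement(
    expert: Mapping[str, int],
    algo: Mapping[str, int],
    replicates: int = 10_000,
    seed: int = 0,
) -> AgreementResult:
    """Full assessment: observed ratio, permutation baseline, t-test."""
    ratio = agreement_ratio(expert, algo)
    baseline = random_baseline(expert, replicates=replicates, seed=seed)
    t, p = one_sample_t_test(baseline, ratio)
    return AgreementResult(
        sample_ratio=ratio,
        baseline_ratios=tuple(baseline),
        baseline_mean=float(np.mean(baseline)),
        t_statistic=t,
        p_value=p,
        permutation_p=permutation_pvalue(baseline, ratio),
        replicates=replicates,
        stars=significance_stars(p),
    )
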