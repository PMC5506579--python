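"""Relevance-feedback loop: multiplicative axis-weight updates.

End users mark retrieved cases as agree/disagree.  Each verdict nudges the
per-axis combination weights with a Hedge-style multiplicative rule: with
y = +1 for agree and -1 for disagree,

    w_a  <-  w_a * exp( eta * y * (sim_a - overall) ),   then renormalize,

so axes that scored the retrieved case above the overall similarity gain
weight on agreement and lose it on disagreement.  The multiplicative form
keeps every weight strictly positive and the renormalization keeps the
vector on the simplex, so repeated updates can never paint the system into
a corner.  The rule itself is a design choice of this package — the
feedback contract only fixes that feedback must tune the weights.

Feedback is persisted append-only as JSON Lines and replayed in timestamp
order, so the final weights are a pure function of the log and the initial
weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .corpus import Corpus, ICTable
from .errors import TaxsimError
from .similarity import AxisWeights, MeasureConfig, axis_combined_similarity
from .taxonomy import Taxonomy

__all__ = [
    "FeedbackRecord",
    "update_axis_weights",
    "combine_with_weights",
    "apply_feedback_events",
    "append_feedback",
    "load_feedback_log",
    "replay_feedback",
]

VERDICTS = ("agree", "disagree")


@dataclass(frozen=True)
class FeedbackRecord:
    """One agree/disagree verdict on a retrieved case."""

    query_id: str
    case_id: str
    verdict: str
    timestamp: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise TaxsimError(f"verdict must be one of {VERDICTS}, got {self.verdict!r}")
        if self.query_id == self.case_id:
            raise TaxsimError("feedback on the query case itself is meaningless")

    @property
    def direction(self) -> int:
        return 1 if self.verdict == "agree" else -1

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "case_id": self.case_id,
            "verdict": self.verdict,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, obj: Mapping) -> "FeedbackRecord":
        return cls(
            obj["query_id"], obj["case_id"], obj["verdict"], obj.get("timestamp", "")
        )


def update_axis_weights(
    weights: AxisWeights,
    record: FeedbackRecord,
    per_axis: Mapping[str, float],
    overall: float,
    learning_rate: float = 0.1,
) -> AxisWeights:
    """Apply one feedback verdict to the axis weights.

    ``per_axis`` holds the axis similarities of the (query, case) pair the
    verdict refers to; ``overall`` their combined score.  Axes absent from
    ``per_axis`` (unannotated on both sides) keep their raw weight and only
    feel the final renormalization.
    """
    if learning_rate < 0:
        raise TaxsimError("learning_rate must be non-negative")
    y = record.direction
    updated = {
        axis_id: w
        * math.exp(learning_rate * y * (per_axis[axis_id] - overall))
        if axis_id in per_axis
        else w
        for axis_id, w in weights.weights.items()
    }
    return AxisWeights(updated)  # constructor renormalizes


def combine_with_weights(
    weights: AxisWeights, per_axis: Mapping[str, float]
) -> float:
    """Overall similarity from per-axis scores under the given weights,
    renormalized over the axes actually scored."""
    if not per_axis:
        return 0.0
    w = weights.restricted(per_axis.keys())
    return sum(w[a] * s for a, s in per_axis.items())


def apply_feedback_events(
    weights: AxisWeights,
    events: Iterable[tuple[FeedbackRecord, Mapping[str, float]]],
    learning_rate: float = 0.1,
) -> AxisWeights:
    """Fold precomputed (record, per-axis similarity) events into the
    weights, rescoring the overall with the weights current at each step."""
    for record, per_axis in events:
        overall = combine_with_weights(weights, per_axis)
        weights = update_axis_weights(weights, record, per_axis, overall, learning_rate)
    return weights


def append_feedback(path: str | Path, record: FeedbackRecord) -> None:
    """Append one record to the JSON Lines feedback log."""
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record.to_dict()) + "\n")


def load_feedback_log(path: str | Path) -> list[FeedbackRecord]:
    records = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            records.append(FeedbackRecord.from_dict(json.loads(line)))
    return records


def replay_feedback(
    weights: AxisWeights,
    records: Iterable[FeedbackRecord],
    corpus: Corpus,
    ic: ICTable,
    taxonomy: Taxonomy,
    config: MeasureConfig = MeasureConfig(),
    learning_rate: float = 0.1,
) -> AxisWeights:
    """Apply a feedback log in timestamp order, rescoring each pair with the
    weights current at that point.  Deterministic: same log + same initial
    weights give the same final weights."""
    ordered = sorted(records, key=lambda r: (r.timestamp, r.query_id, r.case_id))
    for record in ordered:
        overall, per_axis = axis_combined_similarity(
            corpus[record.query_id],
            corpus[record.case_id],
            weights,
            config,
            ic,
            taxonomy,
        )
        weights = update_axis_weights(
            weights, record, per_axis, overall, learning_rate
        )
    return weights
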