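"""Annotated case reports and per-axis information content.

A corpus is a collection of case reports, each carrying one annotation set
per taxonomy axis.  Term usage statistics are obtained by propagating direct
annotations up the DAG (a case annotated with a term implicitly instantiates
every ancestor of that term), from which the information content

    IC(t) = -ln( p(t) ),    p(t) = count(t) / N_axis

is estimated per axis.  ``N_axis`` is the number of cases with at least one
annotation on that axis, not the whole-corpus size: axes differ in coverage
and similarities are computed per axis before being combined.

Terms never observed in the corpus receive the finite floor
``-ln(1 / (2 * N_axis))`` — half a pseudo-count — instead of an infinite IC,
which keeps Lin similarity defined everywhere on small, sparse corpora.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

from .errors import CorpusError, ValidationError
from .taxonomy import Taxonomy

__all__ = [
    "CaseReport",
    "Corpus",
    "ICTable",
    "load_corpus",
    "annotation_frequencies",
    "information_content",
    "build_ic_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CaseReport:
    """One case report: an id plus per-axis sets of direct annotations.

    ``free_text`` carries the narrative (summary/commentary) opaquely; it is
    never analyzed.
    """

    case_id: str
    annotations: Mapping[str, frozenset[str]]
    free_text: str | None = None

    def annotated_axes(self) -> frozenset[str]:
        return frozenset(a for a, ts in self.annotations.items() if ts)


class Corpus:
    """Mapping of case id to :class:`CaseReport`."""

    def __init__(self, cases: list[CaseReport], taxonomy_ref: str | None = None):
        self._cases: dict[str, CaseReport] = {}
        for case in cases:
            if case.case_id in self._cases:
                raise CorpusError(f"duplicate case id {case.case_id!r}")
            self._cases[case.case_id] = case
        self.taxonomy_ref = taxonomy_ref

    @property
    def cases(self) -> Mapping[str, CaseReport]:
        return self._cases

    def __len__(self) -> int:
        return len(self._cases)

    def __iter__(self) -> Iterator[str]:
        return iter(self._cases)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self._cases

    def __getitem__(self, case_id: str) -> CaseReport:
        try:
            return self._cases[case_id]
        except KeyError:
            raise CorpusError(f"unknown case {case_id!r}") from None

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for case in self._cases.values():
            for axis_id in sorted(case.annotations):
                for term_id in sorted(case.annotations[axis_id]):
                    rows.append((case.case_id, axis_id, term_id))
        pd.DataFrame(rows, columns=["case_id", "axis_id", "term_id"]).to_csv(
            path, index=False
        )


@dataclass
class ICTable:
    """Propagated annotation counts and per-term information content (nats)."""

    counts: dict[str, int]
    axis_totals: dict[str, int]
    ic: dict[str, float] = field(default_factory=dict)
    # memo for Lin term-pair scores; not part of the value semantics
    _lin_cache: dict = field(default_factory=dict, repr=False, compare=False)


def load_corpus(source: str | Path, taxonomy: Taxonomy) -> Corpus:
    """Load a corpus from CSV (``case_id,axis_id,term_id``) or JSON Lines.

    Every annotation is validated against the taxonomy: unknown terms and
    terms filed under the wrong axis raise :class:`ValidationError` listing
    all offenders.  Duplicate annotations within one case's axis are
    deduplicated with a logged warning.
    """
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        raw = _read_csv(path)
    elif suffix in (".jsonl", ".ndjson"):
        raw = _read_jsonl(path)
    else:
        raise CorpusError(
            f"cannot infer corpus dialect from extension {suffix!r}; "
            "expected .csv or .jsonl"
        )
    return _build_corpus(raw, taxonomy)


def _read_csv(path: Path) -> list[tuple[str, str, str, str | None]]:
    df = pd.read_csv(path, dtype=str)
    required = {"case_id", "axis_id", "term_id"}
    if not required.issubset(df.columns):
        raise CorpusError(f"corpus CSV must have columns {sorted(required)}")
    return [(r.case_id, r.axis_id, r.term_id, None) for r in df.itertuples()]


def _read_jsonl(path: Path) -> list[tuple[str, str, str, str | None]]:
    rows: list[tuple[str, str, str, str | None]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        obj = json.loads(line)
        case_id = obj["case_id"]
        if case_id in seen:
            raise CorpusError(f"{path.name}:{lineno}: duplicate case id {case_id!r}")
        seen.add(case_id)
        text = obj.get("free_text")
        annotations = obj.get("annotations", {})
        if not annotations:
            rows.append((case_id, "", "", text))
        for axis_id, term_ids in annotations.items():
            for term_id in term_ids:
                rows.append((case_id, axis_id, term_id, text))
    return rows


def _build_corpus(
    raw: list[tuple[str, str, str, str | None]], taxonomy: Taxonomy
) -> Corpus:
    offenders: list[str] = []
    per_case: dict[str, dict[str, set[str]]] = {}
    texts: dict[str, str | None] = {}
    n_dupes = 0
    for case_id, axis_id, term_id, text in raw:
        texts.setdefault(case_id, text)
        annotations = per_case.setdefault(case_id, {})
        if not term_id:
            continue  # case declared with no annotations
        if term_id not in taxonomy:
            offenders.append(f"{case_id}: unknown term {term_id!r}")
            continue
        if taxonomy.axis_of(term_id) != axis_id:
            offenders.append(
                f"{case_id}: term {term_id!r} filed under {axis_id!r} but "
                f"belongs to {taxonomy.axis_of(term_id)!r}"
            )
            continue
        axis_terms = annotations.setdefault(axis_id, set())
        if term_id in axis_terms:
            n_dupes += 1
            logger.warning(
                "case %s: duplicate annotation %s on axis %s dropped",
                case_id, term_id, axis_id,
            )
        axis_terms.add(term_id)
    if offenders:
        raise ValidationError(
            "corpus failed validation:\n  " + "\n  ".join(offenders)
        )
    if n_dupes:
        logger.warning("dropped %d duplicate annotations in total", n_dupes)
    cases = [
        CaseReport(
            case_id,
            {a: frozenset(ts) for a, ts in annotations.items()},
            texts[case_id],
        )
        for case_id, annotations in per_case.items()
    ]
    return Corpus(cases)


def annotation_frequencies(corpus: Corpus, taxonomy: Taxonomy) -> ICTable:
    """Propagated per-term annotation counts and per-axis case totals.

    ``count(t)`` is the number of *distinct* cases annotated with ``t`` or any
    descendant of ``t`` — each case counts once per term no matter how many of
    its annotations fall below that term.  ``axis_total(a)`` is the number of
    cases with at least one annotation on axis ``a``.
    """
    if len(corpus) == 0:
        raise CorpusError("cannot compute frequencies over an empty corpus")
    counts = {term_id: 0 for term_id in taxonomy}
    axis_totals = {axis_id: 0 for axis_id in taxonomy.axes}
    for case in corpus.cases.values():
        for axis_id, direct in case.annotations.items():
            if not direct:
                continue
            axis_totals[axis_id] += 1
            instantiated: set[str] = set()
            for term_id in direct:
                instantiated |= taxonomy.ancestors(term_id, include_self=True)
            for term_id in instantiated:
                counts[term_id] += 1
    return ICTable(counts=counts, axis_totals=axis_totals)


def information_content(table: ICTable, taxonomy: Taxonomy) -> ICTable:
    """Fill per-term IC values in nats; returns the same table.

    Requires ``axis_total > 0`` for every axis that carries terms with
    nonzero counts; unobserved terms get the half-pseudo-count floor.
    """
    ic: dict[str, float] = {}
    for term_id in taxonomy:
        axis_id = taxonomy.axis_of(term_id)
        total = table.axis_totals.get(axis_id, 0)
        count = table.counts.get(term_id, 0)
        if total <= 0:
            if count > 0:
                raise CorpusError(
                    f"axis {axis_id!r} has zero annotated cases but nonzero counts"
                )
            ic[term_id] = 0.0
            continue
        if count > 0:
            # "or 0.0" normalizes the -0.0 that -log(1.0) produces
            ic[term_id] = -math.log(count / total) or 0.0
        else:
            ic[term_id] = -math.log(1.0 / (2.0 * total))
    table.ic = ic
    return table


def build_ic_table(corpus: Corpus, taxonomy: Taxonomy) -> ICTable:
    """Convenience: frequencies + information content in one call."""
    return information_content(annotation_frequencies(corpus, taxonomy), taxonomy)
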