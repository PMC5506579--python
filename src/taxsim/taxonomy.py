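"""Multi-axis taxonomy: loading, validation and ancestor traversal.

The taxonomy is a forest of rooted directed acyclic graphs, one DAG per
*axis* (the "perspectives" under which a case report is annotated, e.g.
``safety_target``).  Terms may have several parents within their axis but
never across axes: per-axis similarities are computed independently and
combined afterwards, so cross-axis term pairs share no ancestors by
construction.

Three on-disk dialects are supported, selected by file extension:

``.obo``
    OBO-style stanzas; ``namespace:`` carries the axis id.
``.json``
    ``{"terms": [{"id", "label", "axis", "parents": [...]}, ...]}``.
``.tsv``
    Edge list ``child<TAB>parent<TAB>axis``; roots may be declared with an
    empty parent field.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet

from .errors import (
    AxisPartitionError,
    CycleError,
    DanglingReferenceError,
    TaxonomyError,
    UnknownTermError,
)

__all__ = ["Term", "Axis", "Taxonomy", "load_taxonomy"]


@dataclass(frozen=True)
class Term:
    """A single taxonomy concept.

    Parameters
    ----------
    term_id
        Unique token identifying the term.
    label
        Human-readable name; free text, not interpreted.
    axis_id
        The axis (perspective) the term belongs to.
    parent_ids
        Direct parents; empty for the axis root.
    """

    term_id: str
    label: str
    axis_id: str
    parent_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise TaxonomyError("term_id must be non-empty")
        if not self.axis_id:
            raise TaxonomyError(f"term {self.term_id!r}: axis_id must be non-empty")


@dataclass(frozen=True)
class Axis:
    """One perspective of the taxonomy: a rooted DAG of terms."""

    axis_id: str
    root_id: str
    term_ids: frozenset[str]


class Taxonomy:
    """A validated multi-axis taxonomy with cached ancestor closure."""

    def __init__(self, terms: Iterable[Term]):
        self._terms: dict[str, Term] = {}
        for term in terms:
            if term.term_id in self._terms:
                raise TaxonomyError(f"duplicate term id {term.term_id!r}")
            self._terms[term.term_id] = term
        if not self._terms:
            raise TaxonomyError("taxonomy contains no terms")
        self._validate_references()
        self._graph = self._build_graph()
        self._validate_acyclic()
        self._axes = self._build_axes()
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers -------------------------------------------------

    def _validate_references(self) -> None:
        for term in self._terms.values():
            for pid in term.parent_ids:
                parent = self._terms.get(pid)
                if parent is None:
                    raise DanglingReferenceError(
                        f"term {term.term_id!r} references unknown parent {pid!r}"
                    )
                if parent.axis_id != term.axis_id:
                    raise AxisPartitionError(
                        f"edge {term.term_id!r} -> {pid!r} crosses axes "
                        f"{term.axis_id!r} and {parent.axis_id!r}"
                    )

    def _build_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()  # edges point child -> parent
        g.add_nodes_from(self._terms)
        for term in self._terms.values():
            for pid in term.parent_ids:
                g.add_edge(term.term_id, pid)
        return g

    def _validate_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise CycleError(
                f"parent relation contains a cycle through {cycle[0][0]!r}"
            )

    def _build_axes(self) -> dict[str, Axis]:
        members: dict[str, set[str]] = {}
        roots: dict[str, list[str]] = {}
        for term in self._terms.values():
            members.setdefault(term.axis_id, set()).add(term.term_id)
            if not term.parent_ids:
                roots.setdefault(term.axis_id, []).append(term.term_id)
        axes: dict[str, Axis] = {}
        for axis_id, term_ids in members.items():
            axis_roots = roots.get(axis_id, [])
            if len(axis_roots) != 1:
                raise AxisPartitionError(
                    f"axis {axis_id!r} has {len(axis_roots)} roots, expected 1"
                )
            axes[axis_id] = Axis(axis_id, axis_roots[0], frozenset(term_ids))
        return axes

    # -- basic accessors ------------------------------------------------------

    @property
    def terms(self) -> Mapping[str, Term]:
        return self._terms

    @property
    def axes(self) -> Mapping[str, Axis]:
        return self._axes

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    def axis_of(self, term_id: str) -> str:
        return self[term_id].axis_id

    def __getitem__(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term {term_id!r}") from None

    # -- traversal ------------------------------------------------------------

    def ancestors(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """Transitive closure of the parent relation within the term's axis.

        Contains the axis root for every non-root term; contains ``term_id``
        itself iff ``include_self``.
        """
        self[term_id]  # raise on unknown term
        closure = self._anc_cache.get(term_id)
        if closure is None:
            closure = frozenset(nx.descendants(self._graph, term_id))
            self._anc_cache[term_id] = closure
        return closure | {term_id} if include_self else closure

    def descendants(self, term_id: str, include_self: bool = False) -> frozenset[str]:
        """Transitive closure of the child relation (inverse of ancestors)."""
        self[term_id]
        closure = self._desc_cache.get(term_id)
        if closure is None:
            closure = frozenset(nx.ancestors(self._graph, term_id))
            self._desc_cache[term_id] = closure
        return closure | {term_id} if include_self else closure

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        """Shared ancestors of two terms, *both terms included*.

        Self-inclusion is the convention the most-informative-common-ancestor
        (MICA) computation requires: a term is its own best common ancestor
        when compared with itself or with a descendant.  Terms from different
        axes share nothing and yield the empty set.
        """
        if self.axis_of(t1) != self.axis_of(t2):
            return frozenset()
        return self.ancestors(t1, include_self=True) & self.ancestors(
            t2, include_self=True
        )

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "axes": sorted(self._axes),
            "terms": [
                {
                    "id": t.term_id,
                    "label": t.label,
                    "axis": t.axis_id,
                    "parents": sorted(t.parent_ids),
                }
                for t in sorted(self._terms.values(), key=lambda t: t.term_id)
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = []
        for term in sorted(self._terms.values(), key=lambda t: t.term_id):
            if term.parent_ids:
                for pid in sorted(term.parent_ids):
                    lines.append(f"{term.term_id}\t{pid}\t{term.axis_id}")
            else:
                lines.append(f"{term.term_id}\t\t{term.axis_id}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


# -- loaders ------------------------------------------------------------------


def load_taxonomy(source: str | Path) -> Taxonomy:
    """Load and validate a taxonomy document.

    The dialect is selected by file extension (``.obo``, ``.json``, ``.tsv``);
    any other extension raises rather than guessing.
    """
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix == ".obo":
        terms = _parse_obo(path)
    elif suffix == ".json":
        terms = _parse_json(path)
    elif suffix in (".tsv", ".txt"):
        terms = _parse_tsv(path)
    else:
        raise TaxonomyError(
            f"cannot infer taxonomy dialect from extension {suffix!r}; "
            "expected .obo, .json or .tsv"
        )
    return Taxonomy(terms)


def _parse_obo(path: Path) -> list[Term]:
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms = []
    for node, data in graph.nodes(data=True):
        axis = data.get("namespace")
        if not axis:
            raise AxisPartitionError(f"OBO term {node!r} declares no namespace (axis)")
        parents = frozenset(data.get("is_a", []))
        terms.append(Term(node, data.get("name", node), axis, parents))
    return terms


def _parse_json(path: Path) -> list[Term]:
    doc = json.loads(path.read_text(encoding="utf-8"))
    terms = []
    for entry in doc["terms"]:
        terms.append(
            Term(
                entry["id"],
                entry.get("label", entry["id"]),
                entry["axis"],
                frozenset(entry.get("parents", [])),
            )
        )
    return terms


def _parse_tsv(path: Path) -> list[Term]:
    parents: dict[str, set[str]] = {}
    axes: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise TaxonomyError(f"{path.name}:{lineno}: expected 3 tab-separated fields")
        child, parent, axis = (f.strip() for f in fields)
        for node in (child, parent):
            if not node:
                continue
            if axes.setdefault(node, axis) != axis:
                raise AxisPartitionError(
                    f"term {node!r} assigned to axes {axes[node]!r} and {axis!r}"
                )
            parents.setdefault(node, set())
        if parent:
            parents[child].add(parent)
    return [
        Term(node, node, axes[node], frozenset(parents[node])) for node in parents
    ]
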