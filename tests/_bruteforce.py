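"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's traversal caches and vectorized
paths: ancestor closure by naive recursion over ``Term.parent_ids``, Lin by
exhaustive enumeration of common ancestors, NTO/VS by plain set and float
arithmetic.
"""

from __future__ import annotations

import math


def bf_ancestors(taxonomy, term_id: str, include_self: bool = False) -> set[str]:
    out: set[str] = set()

    def walk(t: str) -> None:
        for p in taxonomy.terms[t].parent_ids:
            if p not in out:
                out.add(p)
                walk(p)

    walk(term_id)
    if include_self:
        out.add(term_id)
    return out


def bf_common_ancestors(taxonomy, t1: str, t2: str) -> set[str]:
    if taxonomy.terms[t1].axis_id != taxonomy.terms[t2].axis_id:
        return set()
    return bf_ancestors(taxonomy, t1, True) & bf_ancestors(taxonomy, t2, True)


def bf_lin(ic, taxonomy, t1: str, t2: str) -> float:
    common = bf_common_ancestors(taxonomy, t1, t2)
    if not common:
        return 0.0
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        return 1.0 if t1 == t2 else 0.0
    best = max(ic.ic[a] for a in common)
    return 2.0 * best / denom


def bf_pairwise_average(ic, taxonomy, A, B) -> float:
    if not A or not B:
        return 0.0
    scores = [bf_lin(ic, taxonomy, a, b) for a in A for b in B]
    return sum(scores) / len(scores)


def bf_nto(taxonomy, A, B, include_root: bool = False) -> float:
    if not A or not B:
        return 0.0
    axis = taxonomy.terms[next(iter(A))].axis_id
    root = taxonomy.axes[axis].root_id
    a_ext = set().union(*(bf_ancestors(taxonomy, t, True) for t in A))
    b_ext = set().union(*(bf_ancestors(taxonomy, t, True) for t in B))
    if not include_root:
        a_ext -= {root}
        b_ext -= {root}
    if not a_ext or not b_ext:
        return 0.0
    return len(a_ext & b_ext) / min(len(a_ext), len(b_ext))


def bf_vs(taxonomy, ic, A, B, weighting: str = "binary",
          extend_ancestors: bool = False) -> float:
    if not A or not B:
        return 0.0
    if extend_ancestors:
        A = set().union(*(bf_ancestors(taxonomy, t, True) for t in A))
        B = set().union(*(bf_ancestors(taxonomy, t, True) for t in B))

    def weight(t: str) -> float:
        return ic.ic[t] if weighting == "frequency" else 1.0

    dot = sum(weight(t) * weight(t) for t in set(A) & set(B))
    na = math.sqrt(sum(weight(t) ** 2 for t in A))
    nb = math.sqrt(sum(weight(t) ** 2 for t in B))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return min(1.0, dot / (na * nb))


def bf_propagated_counts(corpus, taxonomy) -> dict[str, int]:
    counts = {t: 0 for t in taxonomy.terms}
    for case in corpus.cases.values():
        hit: set[str] = set()
        for terms in case.annotations.values():
            for t in terms:
                hit |= bf_ancestors(taxonomy, t, True)
        for t in hit:
            counts[t] += 1
    return counts
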