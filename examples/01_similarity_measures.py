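"""Compare two annotation sets with the three similarity measures.

Builds a four-term diamond taxonomy (root R, children X and Y, leaf Z under
both), a two-case corpus to estimate information content, and scores the
sets {Z} vs {X} with each measure.
"""

from taxsim import (
    CaseReport,
    Corpus,
    Taxonomy,
    Term,
    build_ic_table,
    lin_similarity,
    nto_similarity,
    pairwise_average_similarity,
    vs_similarity,
)

taxonomy = Taxonomy(
    [
        Term("R", "root", "ax", frozenset()),
        Term("X", "x", "ax", frozenset({"R"})),
        Term("Y", "y", "ax", frozenset({"R"})),
        Term("Z", "z", "ax", frozenset({"X", "Y"})),
    ]
)
corpus = Corpus(
    [
        CaseReport("c1", {"ax": frozenset({"Z"})}),
        CaseReport("c2", {"ax": frozenset({"X"})}),
    ]
)
ic = build_ic_table(corpus, taxonomy)

A, B = frozenset({"Z"}), frozenset({"Y"})
print("term IC values:", {t: round(v, 4) for t, v in sorted(ic.ic.items())})
print(f"Lin(Z, Y)              = {lin_similarity(ic, taxonomy, 'Z', 'Y'):.4f}")
print(f"pairwise-average(A, B) = {pairwise_average_similarity(ic, taxonomy, A, B):.4f}")
print(f"NTO(A, B)              = {nto_similarity(taxonomy, A, B):.4f}")
print(f"VS-binary(A, B)        = {vs_similarity(taxonomy, ic, A, B):.4f}")
print()
print("Y subsumes Z and carries the same information content, so Lin rates")
print("the pair 1; Z's ancestor-extended set {X,Y,Z} fully covers B+ = {Y},")
print("so NTO is 1 as well; the cosine only compares the direct annotations")
print("Z vs Y, which are disjoint, so VS is 0.")
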