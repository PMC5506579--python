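import pytest

from taxsim import (
    AxisWeights,
    CaseReport,
    Corpus,
    SynthConfig,
    Taxonomy,
    Term,
    build_ic_table,
    generate_corpus,
    generate_taxonomy,
)


@pytest.fixture
def diamond_taxonomy() -> Taxonomy:
    """Single axis: root R with children X, Y; Z below both (a true DAG)."""
    return Taxonomy(
        [
            Term("R", "root", "ax", frozenset()),
            Term("X", "x", "ax", frozenset({"R"})),
            Term("Y", "y", "ax", frozenset({"R"})),
            Term("Z", "z", "ax", frozenset({"X", "Y"})),
        ]
    )


@pytest.fixture
def abc_taxonomy() -> Taxonomy:
    """Root A with leaves B and C, plus a second disjoint axis."""
    return Taxonomy(
        [
            Term("A", "a", "ax1", frozenset()),
            Term("B", "b", "ax1", frozenset({"A"})),
            Term("C", "c", "ax1", frozenset({"A"})),
            Term("D", "d", "ax2", frozenset()),
            Term("E", "e", "ax2", frozenset({"D"})),
        ]
    )


@pytest.fixture
def abc_corpus(abc_taxonomy) -> Corpus:
    """Two cases: one annotates B, the other C (axis ax1 only)."""
    return Corpus(
        [
            CaseReport("case1", {"ax1": frozenset({"B"})}),
            CaseReport("case2", {"ax1": frozenset({"C"})}),
        ]
    )


@pytest.fixture(scope="session")
def oracle_pipeline():
    """Seeded 10-case, 30-term corpus with its IC table, for oracle checks."""
    config = SynthConfig(
        n_axes=3, n_terms=30, n_cases=10, n_clusters=2, root_fanout=4, seed=7
    )
    taxonomy = generate_taxonomy(config)
    corpus, truth = generate_corpus(taxonomy, config)
    ic = build_ic_table(corpus, taxonomy)
    return taxonomy, corpus, ic, truth, config


@pytest.fixture(scope="session")
def default_pipeline():
    """The full-scale study conditions: 6 axes, 219 terms, 366 cases."""
    config = SynthConfig(seed=0)  # theme_prob 0.8, rating_noise 0.1 defaults
    taxonomy = generate_taxonomy(config)
    corpus, truth = generate_corpus(taxonomy, config)
    ic = build_ic_table(corpus, taxonomy)
    weights = AxisWeights.equal(sorted(taxonomy.axes))
    return taxonomy, corpus, ic, truth, weights, config
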