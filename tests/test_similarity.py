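"""Similarity measures, weighted combination and ranked retrieval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taxsim import (
    AxisWeights,
    CaseReport,
    Corpus,
    CrossAxisError,
    MeasureConfig,
    TaxsimError,
    axis_combined_similarity,
    build_ic_table,
    lin_similarity,
    nto_similarity,
    pairwise_average_similarity,
    rank_similar_cases,
    vs_similarity,
)

from ._bruteforce import bf_lin, bf_nto, bf_pairwise_average, bf_vs


@pytest.fixture
def diamond_ic(diamond_taxonomy):
    # two cases annotating the two sides of the diamond give a spread of ICs
    corpus = Corpus(
        [
            CaseReport("c1", {"ax": frozenset({"Z"})}),
            CaseReport("c2", {"ax": frozenset({"X"})}),
        ]
    )
    return build_ic_table(corpus, diamond_taxonomy)


class TestLin:
    def test_self_similarity_is_one(self, diamond_taxonomy, diamond_ic):
        assert diamond_ic.ic["Z"] > 0
        assert lin_similarity(diamond_ic, diamond_taxonomy, "Z", "Z") == 1.0

    def test_siblings_sharing_only_root(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        assert lin_similarity(ic, abc_taxonomy, "B", "C") == 0.0

    def test_cross_axis_is_zero(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        assert lin_similarity(ic, abc_taxonomy, "B", "E") == 0.0

    def test_diamond_matches_exhaustive_mica_search(
        self, diamond_taxonomy, diamond_ic
    ):
        for t1 in diamond_taxonomy:
            for t2 in diamond_taxonomy:
                got = lin_similarity(diamond_ic, diamond_taxonomy, t1, t2)
                assert got == pytest.approx(
                    bf_lin(diamond_ic, diamond_taxonomy, t1, t2), abs=1e-12
                )


class TestPairwiseAverage:
    def test_identical_singletons(self, diamond_taxonomy, diamond_ic):
        s = pairwise_average_similarity(
            diamond_ic, diamond_taxonomy, frozenset({"Z"}), frozenset({"Z"})
        )
        assert s == 1.0

    def test_empty_side_scores_zero(self, diamond_taxonomy, diamond_ic):
        s = pairwise_average_similarity(
            diamond_ic, diamond_taxonomy, frozenset(), frozenset({"Z"})
        )
        assert s == 0.0

    def test_two_by_three_matches_double_loop(self, oracle_pipeline):
        taxonomy, _, ic, _, _ = oracle_pipeline
        axis = sorted(taxonomy.axes)[0]
        terms = sorted(taxonomy.axes[axis].term_ids)
        A, B = frozenset(terms[1:3]), frozenset(terms[3:6])
        got = pairwise_average_similarity(ic, taxonomy, A, B)
        assert got == pytest.approx(bf_pairwise_average(ic, taxonomy, A, B), abs=1e-12)

    def test_cross_axis_rejected(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        with pytest.raises(CrossAxisError):
            pairwise_average_similarity(
                ic, abc_taxonomy, frozenset({"B"}), frozenset({"E"})
            )


class TestNTO:
    def test_identical_sets(self, diamond_taxonomy):
        assert nto_similarity(diamond_taxonomy, frozenset({"Z"}), frozenset({"Z"})) == 1.0

    def test_disjoint_after_root_removal(self, abc_taxonomy):
        assert nto_similarity(abc_taxonomy, frozenset({"B"}), frozenset({"C"})) == 0.0

    def test_diamond_hand_computation(self, diamond_taxonomy):
        # A+ = {X, Y, Z}, B+ = {X} after removing root R -> 1/1
        s = nto_similarity(diamond_taxonomy, frozenset({"Z"}), frozenset({"X"}))
        assert s == 1.0

    def test_include_root_floor(self, abc_taxonomy):
        # with the root retained any same-axis pair shares at least one term
        s = nto_similarity(
            abc_taxonomy, frozenset({"B"}), frozenset({"C"}), include_root=True
        )
        assert s == pytest.approx(0.5)


class TestVS:
    def test_identical_sets(self, diamond_taxonomy, diamond_ic):
        s = vs_similarity(
            diamond_taxonomy, diamond_ic, frozenset({"X", "Z"}), frozenset({"X", "Z"})
        )
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_binary_direct_is_zero(self, diamond_taxonomy, diamond_ic):
        s = vs_similarity(
            diamond_taxonomy, diamond_ic, frozenset({"X"}), frozenset({"Y"})
        )
        assert s == 0.0

    def test_nested_sets_closed_form(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        s = vs_similarity(
            abc_taxonomy, ic, frozenset({"B"}), frozenset({"B", "C"})
        )
        assert s == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_frequency_weighting_requires_ic(self, diamond_taxonomy):
        with pytest.raises(TaxsimError):
            vs_similarity(
                diamond_taxonomy,
                None,
                frozenset({"X"}),
                frozenset({"X"}),
                MeasureConfig(measure="vs", vs_weighting="frequency"),
            )


class TestOracleEquivalence:
    """Every measure matches its brute-force reimplementation on all
    annotation-set pairs of the seeded random corpus."""

    def test_all_measures_all_pairs(self, oracle_pipeline):
        taxonomy, corpus, ic, _, _ = oracle_pipeline
        ids = sorted(corpus.cases)
        for i, c1 in enumerate(ids):
            for c2 in ids[i:]:
                for axis in taxonomy.axes:
                    A = corpus[c1].annotations.get(axis, frozenset())
                    B = corpus[c2].annotations.get(axis, frozenset())
                    assert pairwise_average_similarity(
                        ic, taxonomy, A, B
                    ) == pytest.approx(
                        bf_pairwise_average(ic, taxonomy, A, B), abs=1e-12
                    )
                    assert nto_similarity(taxonomy, A, B) == pytest.approx(
                        bf_nto(taxonomy, A, B), abs=1e-12
                    )
                    for weighting in ("binary", "frequency"):
                        cfg = MeasureConfig(measure="vs", vs_weighting=weighting)
                        assert vs_similarity(
                            taxonomy, ic, A, B, cfg
                        ) == pytest.approx(
                            bf_vs(taxonomy, ic, A, B, weighting), abs=1e-12
                        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(data=st.data())
def test_measures_symmetric_and_bounded(oracle_pipeline, data):
    taxonomy, _, ic, _, _ = oracle_pipeline
    axis = data.draw(st.sampled_from(sorted(taxonomy.axes)))
    terms = sorted(taxonomy.axes[axis].term_ids)
    A = frozenset(data.draw(st.sets(st.sampled_from(terms), max_size=4)))
    B = frozenset(data.draw(st.sets(st.sampled_from(terms), max_size=4)))
    for fn in (
        lambda x, y: pairwise_average_similarity(ic, taxonomy, x, y),
        lambda x, y: nto_similarity(taxonomy, x, y),
        lambda x, y: vs_similarity(taxonomy, ic, x, y),
        lambda x, y: vs_similarity(
            taxonomy, ic, x, y, MeasureConfig(measure="vs", vs_weighting="frequency")
        ),
    ):
        s = fn(A, B)
        assert s == fn(B, A)
        assert 0.0 <= s <= 1.0


class TestAxisCombination:
    @pytest.fixture
    def six_axis_setup(self, default_pipeline):
        taxonomy, corpus, ic, _, weights, _ = default_pipeline
        return taxonomy, corpus, ic, weights

    def test_equal_axis_scores_collapse_to_that_score(
        self, abc_taxonomy, abc_corpus
    ):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        case = CaseReport("q", {"ax1": frozenset({"B"})})
        weights = AxisWeights.equal(["ax1"])
        overall, per_axis = axis_combined_similarity(
            case, case, weights, MeasureConfig(measure="nto"), ic, abc_taxonomy
        )
        assert overall == per_axis["ax1"] == 1.0

    def test_one_of_six_axes_matching(self, six_axis_setup):
        taxonomy, corpus, ic, weights = six_axis_setup
        axes = sorted(taxonomy.axes)
        donor = corpus[sorted(corpus.cases)[0]]
        # same annotations on one axis, disjoint singletons picked from
        # other clusters' space would be fragile; build two synthetic cases
        # that agree on axis 0 and are both annotated but disjoint elsewhere
        ann1, ann2 = {}, {}
        for i, axis in enumerate(axes):
            terms = sorted(taxonomy.axes[axis].term_ids - {taxonomy.axes[axis].root_id})
            if i == 0:
                ann1[axis] = ann2[axis] = frozenset({terms[0]})
            else:
                # two leaves far apart; NTO scores 0 unless they share a
                # non-root ancestor, so pick children of different depth-1 nodes
                ann1[axis] = frozenset({terms[0]})
                ann2[axis] = frozenset({terms[-1]})
        c1, c2 = CaseReport("c1", ann1), CaseReport("c2", ann2)
        overall, per_axis = axis_combined_similarity(
            c1, c2, weights, MeasureConfig(measure="nto"), ic, taxonomy
        )
        expected = sum(per_axis[a] for a in axes) / 6
        assert overall == pytest.approx(expected)
        assert per_axis[axes[0]] == 1.0

    def test_both_empty_axes_excluded_and_renormalized(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        weights = AxisWeights.equal(["ax1", "ax2"])
        c1 = CaseReport("c1", {"ax1": frozenset({"B"})})
        c2 = CaseReport("c2", {"ax1": frozenset({"B"})})
        overall, per_axis = axis_combined_similarity(
            c1, c2, weights, MeasureConfig(measure="nto"), ic, abc_taxonomy
        )
        assert "ax2" not in per_axis  # excluded, weight renormalized to ax1
        assert overall == 1.0

    def test_one_sided_empty_axis_scores_zero(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        weights = AxisWeights.equal(["ax1", "ax2"])
        c1 = CaseReport("c1", {"ax1": frozenset({"B"}), "ax2": frozenset({"E"})})
        c2 = CaseReport("c2", {"ax1": frozenset({"B"})})
        overall, per_axis = axis_combined_similarity(
            c1, c2, weights, MeasureConfig(measure="nto"), ic, abc_taxonomy
        )
        assert per_axis["ax2"] == 0.0
        assert overall == pytest.approx(0.5)

    def test_fully_unannotated_pair_scores_zero(self, abc_taxonomy, abc_corpus):
        ic = build_ic_table(abc_corpus, abc_taxonomy)
        weights = AxisWeights.equal(["ax1", "ax2"])
        c1, c2 = CaseReport("c1", {}), CaseReport("c2", {})
        overall, per_axis = axis_combined_similarity(
            c1, c2, weights, MeasureConfig(measure="nto"), ic, abc_taxonomy
        )
        assert overall == 0.0 and per_axis == {}


class TestRanking:
    def test_duplicate_annotations_rank_first_with_score_one(
        self, abc_taxonomy
    ):
        corpus = Corpus(
            [
                CaseReport("q", {"ax1": frozenset({"B"})}),
                CaseReport("dup", {"ax1": frozenset({"B"})}),
                CaseReport("other", {"ax1": frozenset({"C"})}),
            ]
        )
        ic = build_ic_table(corpus, abc_taxonomy)
        ranked = rank_similar_cases(
            corpus, "q", AxisWeights.equal(["ax1"]),
            MeasureConfig(measure="vs"), ic, abc_taxonomy,
        )
        assert ranked.entries[0] == ("dup", 1.0)
        assert len(ranked.entries) == len(corpus) - 1

    def test_ties_broken_by_case_id_ascending(self, abc_taxonomy):
        corpus = Corpus(
            [
                CaseReport("q", {"ax1": frozenset({"B"})}),
                CaseReport("b_case", {"ax1": frozenset({"C"})}),
                CaseReport("a_case", {"ax1": frozenset({"C"})}),
            ]
        )
        ic = build_ic_table(corpus, abc_taxonomy)
        ranked = rank_similar_cases(
            corpus, "q", AxisWeights.equal(["ax1"]),
            MeasureConfig(measure="vs"), ic, abc_taxonomy,
        )
        assert [c for c, _ in ranked.entries] == ["a_case", "b_case"]

    def test_axis_filter_unknown_axis_rejected(self, default_pipeline):
        taxonomy, corpus, ic, _, weights, _ = default_pipeline
        with pytest.raises(TaxsimError):
            rank_similar_cases(
                corpus, "case_001", weights, MeasureConfig(), ic, taxonomy,
                axis_filter=["not_an_axis"],
            )

    def test_ranking_matches_bruteforce_recomputation(self, oracle_pipeline):
        taxonomy, corpus, ic, _, _ = oracle_pipeline
        weights = AxisWeights.equal(sorted(taxonomy.axes))
        config = MeasureConfig(measure="nto")
        ranked = rank_similar_cases(
            corpus, sorted(corpus.cases)[0], weights, config, ic, taxonomy
        )
        query = corpus[sorted(corpus.cases)[0]]
        for case_id, score in ranked.entries:
            per_axis = {}
            for axis in sorted(taxonomy.axes):
                A = query.annotations.get(axis, frozenset())
                B = corpus[case_id].annotations.get(axis, frozenset())
                if A or B:
                    per_axis[axis] = bf_nto(taxonomy, A, B)
            expected = (
                sum(per_axis.values()) / len(per_axis) if per_axis else 0.0
            )
            assert score == pytest.approx(expected, abs=1e-12)

    def test_planted_clusters_raise_within_cluster_similarity(
        self, default_pipeline
    ):
        taxonomy, corpus, ic, truth, weights, _ = default_pipeline
        ids = sorted(corpus.cases)[:60]
        for measure in ("ic", "nto", "vs"):
            config = MeasureConfig(measure=measure)
            within, between = [], []
            for i, c1 in enumerate(ids):
                for c2 in ids[i + 1 :: 7]:
                    s, _ = axis_combined_similarity(
                        corpus[c1], corpus[c2], weights, config, ic, taxonomy
                    )
                    bucket = (
                        within
                        if truth.assignment[c1] == truth.assignment[c2]
                        else between
                    )
                    bucket.append(s)
            assert np.mean(within) > np.mean(between)
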