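"""Similarity-weighted alignment, metrics and the unseen protocol."""

import logging
import math

import numpy as np
import pytest

from paratag import (
    Annotation,
    Span,
    align_and_count,
    char_jaccard,
    compute_metrics,
    concept_similarity,
    evaluate,
    filter_unseen,
)
from paratag.evaluation import EvalCounts, pair_similarity
from paratag.errors import IntegrityError, ParameterError

from conftest import (
    bruteforce_best_match,
    perturbed_predictions,
    random_annotation_set,
)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([(0, 10)], [(0, 10)], 1.0),
        ([(0, 4)], [(2, 6)], 1 / 3),
        ([(0, 2)], [(5, 7)], 0.0),
        ([(0, 2), (15, 20)], [(0, 2), (15, 20)], 1.0),
    ],
)
def test_char_jaccard(a, b, expected):
    sa, sb = [Span(*t) for t in a], [Span(*t) for t in b]
    assert char_jaccard(sa, sb) == pytest.approx(expected)


class TestConceptSimilarity:
    def test_identity(self, tiny_ontology):
        assert concept_similarity("T:X", "T:X", tiny_ontology) == 1.0

    def test_siblings_share_half_their_ancestry(self, tiny_ontology):
        # ancestor sets {X,P,R} and {Y,P,R}: overlap 2 of 4
        assert concept_similarity("T:X", "T:Y", tiny_ontology) == 0.5

    def test_disjoint_trees(self, tiny_ontology):
        assert concept_similarity("T:X", "T:Q", tiny_ontology) == 0.0

    def test_missing_id_warns_and_scores_zero(self, tiny_ontology, caplog):
        with caplog.at_level(logging.WARNING):
            assert concept_similarity("T:X", "GHOST:1", tiny_ontology) == 0.0
        assert "GHOST:1" in caplog.text


class TestAlignAndCount:
    def test_identical_sets(self, tiny_ontology):
        ref = [Annotation(f"T{i}", "T:X", [(10 * i, 10 * i + 5)])
               for i in range(4)]
        counts = align_and_count(ref, ref, tiny_ontology)
        assert (counts.M, counts.S, counts.I, counts.D) == (4.0, 0.0, 0, 0)

    def test_half_overlap_same_concept(self, tiny_ontology):
        ref = [Annotation("T1", "T:X", [(0, 10)])]
        pred = [Annotation("P1", "T:X", [(0, 5)])]
        counts = align_and_count(ref, pred, tiny_ontology)
        assert counts.M == pytest.approx(0.5)
        assert counts.S == pytest.approx(0.5)
        assert (counts.I, counts.D) == (0, 0)

    def test_wrong_concept_full_overlap_is_substitution(self, tiny_ontology):
        ref = [Annotation("T1", "T:X", [(0, 10)])]
        pred = [Annotation("P1", "T:Q", [(0, 10)])]  # disjoint tree: c = 0
        counts = align_and_count(ref, pred, tiny_ontology)
        assert counts.M == pytest.approx(0.0)
        assert counts.S == pytest.approx(1.0)
        assert (counts.I, counts.D) == (0, 0)

    def test_overlapping_side_rejected(self, tiny_ontology):
        bad = [
            Annotation("T1", "T:X", [(0, 10)]),
            Annotation("T2", "T:Y", [(5, 15)]),
        ]
        with pytest.raises(IntegrityError):
            align_and_count(bad, [], tiny_ontology)

    def test_count_conservation_on_random_sets(self, synthetic_ontology):
        ids = sorted(synthetic_ontology.ids)
        rng = np.random.default_rng(17)
        for _ in range(50):
            ref = random_annotation_set(rng, ids)
            pred = perturbed_predictions(rng, ref, ids)
            counts = align_and_count(ref, pred, synthetic_ontology)
            assert counts.n_reference == pytest.approx(len(ref))
            assert counts.n_predicted == pytest.approx(len(pred))

    def test_similarity_bounds(self, synthetic_ontology):
        ids = sorted(synthetic_ontology.ids)
        rng = np.random.default_rng(19)
        for _ in range(50):
            ref = random_annotation_set(rng, ids)
            pred = perturbed_predictions(rng, ref, ids)
            for r in ref:
                for p in pred:
                    sim = pair_similarity(r, p, synthetic_ontology)
                    assert 0 <= sim.m <= sim.j <= 1
                    assert 0 <= sim.m <= sim.c <= 1
                    exact = (r.spans == p.spans
                             and r.concept_id == p.concept_id)
                    assert (sim.m == 1.0) == exact

    def test_greedy_within_factor_two_of_bruteforce(self, synthetic_ontology):
        """Greedy alignment is bounded below by half the optimum (the
        classic greedy-matching guarantee) and never exceeds it."""
        ids = sorted(synthetic_ontology.ids)
        rng = np.random.default_rng(29)
        for _ in range(60):
            ref = random_annotation_set(rng, ids)
            pred = perturbed_predictions(rng, ref, ids)
            counts = align_and_count(ref, pred, synthetic_ontology)
            optimal = bruteforce_best_match(ref, pred, synthetic_ontology)
            assert counts.M <= optimal + 1e-9
            assert counts.M >= optimal / 2 - 1e-9


class TestComputeMetrics:
    def test_perfect(self):
        m = compute_metrics(EvalCounts(1, 0, 0, 0))
        assert (m.precision, m.recall, m.f_score, m.ser) == (1, 1, 1, 0)

    def test_half_match(self):
        m = compute_metrics(EvalCounts(0.5, 0.5, 0, 0))
        assert m.precision == m.recall == m.f_score == pytest.approx(0.5)
        assert m.ser == pytest.approx(0.5)

    def test_both_sides_empty_is_vacuously_perfect(self):
        m = compute_metrics(EvalCounts(0, 0, 0, 0))
        assert (m.precision, m.recall, m.f_score, m.ser) == (1, 1, 1, 0)

    def test_empty_reference_with_predictions_flags_ser_undefined(self):
        m = compute_metrics(EvalCounts(0, 0, 3, 0))
        assert (m.precision, m.recall, m.f_score) == (0, 0, 0)
        assert m.ser is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            compute_metrics(EvalCounts(-1, 0, 0, 0))

    def test_swap_symmetry_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            M, S = rng.uniform(0, 5, 2)
            I, D = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            m1 = compute_metrics(EvalCounts(M, S, I, D))
            m2 = compute_metrics(EvalCounts(M, S, D, I))
            assert m1.precision == pytest.approx(m2.recall)
            assert m1.recall == pytest.approx(m2.precision)
            assert m1.f_score == pytest.approx(m2.f_score)

    def test_ser_equals_one_minus_recall_without_insertions(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            M, S = rng.uniform(0, 5, 2)
            counts = EvalCounts(M, S, 0, int(rng.integers(0, 5)))
            m = compute_metrics(counts)
            if counts.n_reference > 0:
                assert m.ser == pytest.approx(1 - m.recall)


class TestFilterUnseenAndEvaluate:
    def test_filter_keeps_only_novel_concepts(self):
        anns = [Annotation(f"T{i}", cid, [(10 * i, 10 * i + 2)])
                for i, cid in enumerate(["C:a", "C:c", "C:b", "C:c"])]
        kept = filter_unseen(anns, {"C:a", "C:b"})
        assert [a.concept_id for a in kept] == ["C:c", "C:c"]
        assert filter_unseen(anns, set()) == anns
        assert filter_unseen(anns, {"C:a", "C:b", "C:c"}) == []

    def test_perfect_prediction(self, tiny_ontology):
        ref = [Annotation("T1", "T:X", [(0, 5)])]
        metrics, _ = evaluate(ref, ref, tiny_ontology)
        assert metrics.f_score == 1.0 and metrics.ser == 0.0

    def test_unseen_filter_covering_nothing_matches_unfiltered(
        self, tiny_ontology
    ):
        ref = [Annotation("T1", "T:X", [(0, 5)]),
               Annotation("T2", "T:Y", [(8, 12)])]
        pred = [Annotation("P1", "T:X", [(0, 5)])]
        unfiltered, _ = evaluate(ref, pred, tiny_ontology)
        filtered, _ = evaluate(ref, pred, tiny_ontology, unseen_of={"T:Q"})
        assert filtered == unfiltered

    def test_insertion_monotonicity(self, tiny_ontology):
        ref = [Annotation("T1", "T:X", [(0, 5)])]
        pred = [Annotation("P1", "T:X", [(0, 5)])]
        base, _ = evaluate(ref, pred, tiny_ontology)
        spurious = pred + [Annotation("P2", "T:Y", [(50, 55)])]
        worse, _ = evaluate(ref, spurious, tiny_ontology)
        assert worse.precision < base.precision
        assert worse.recall == base.recall
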