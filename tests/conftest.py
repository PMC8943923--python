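"""Shared fixtures: tiny ontologies, random annotation sets, profiles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from paratag import Annotation, Concept, Ontology, Span
from paratag.fixtures import CorpusSpec, gen_corpus, gen_ontology

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_ontology() -> Ontology:
    """R <- P <- {X, Y}; Q in a second, disjoint tree."""
    return Ontology({
        "T:R": Concept("T:R", "root", frozenset({"root"}), frozenset()),
        "T:P": Concept("T:P", "parent", frozenset({"parent"}), frozenset({"T:R"})),
        "T:X": Concept("T:X", "xterm", frozenset({"xterm"}), frozenset({"T:P"})),
        "T:Y": Concept("T:Y", "yterm", frozenset({"yterm"}), frozenset({"T:P"})),
        "T:Q": Concept("T:Q", "qterm", frozenset({"qterm"}), frozenset()),
    })


@pytest.fixture(scope="session")
def synthetic_ontology() -> Ontology:
    return gen_ontology(20, seed=11)


@pytest.fixture(scope="session")
def synthetic_corpus(synthetic_ontology):
    spec = CorpusSpec(
        n_docs=3, sentences_per_doc=6, mention_rate=0.9,
        p_discontinuous=0.15, p_overlap=0.15, p_ambiguous_surface=0.1,
        unseen_fraction=0.3, seed=23,
    )
    return gen_corpus(synthetic_ontology, spec)


def random_annotation_set(
    rng: np.random.Generator,
    concept_ids: list[str],
    max_annotations: int = 6,
    text_length: int = 80,
) -> list[Annotation]:
    """Non-overlapping annotations scattered over a coordinate space."""
    annotations = []
    cursor = int(rng.integers(0, 4))
    n = int(rng.integers(0, max_annotations + 1))
    for k in range(n):
        length = int(rng.integers(1, 9))
        if cursor + length > text_length:
            break
        cid = concept_ids[int(rng.integers(len(concept_ids)))]
        annotations.append(
            Annotation(f"T{k + 1}", cid, [(cursor, cursor + length)])
        )
        cursor += length + int(rng.integers(1, 6))
    return annotations


def perturbed_predictions(
    rng: np.random.Generator,
    reference: list[Annotation],
    concept_ids: list[str],
    text_length: int = 80,
) -> list[Annotation]:
    """Predictions derived from a reference by boundary shifts, ID swaps,
    drops and spurious additions, kept non-overlapping."""
    taken: list[Span] = []
    predictions = []

    def admit(start: int, end: int, cid: str) -> None:
        span = Span(start, end)
        if any(span.overlaps(t) for t in taken):
            return
        taken.append(span)
        predictions.append(Annotation(f"P{len(predictions)}", cid, [span]))

    for ann in reference:
        if rng.random() < 0.2:
            continue  # dropped -> deletion
        start, end = ann.start, ann.end
        if rng.random() < 0.4:
            start = max(0, start + int(rng.integers(-2, 3)))
            end = max(start + 1, end + int(rng.integers(-2, 3)))
        cid = ann.concept_id
        if rng.random() < 0.3:
            cid = concept_ids[int(rng.integers(len(concept_ids)))]
        admit(start, end, cid)
    for _ in range(int(rng.integers(0, 3))):  # spurious -> insertions
        start = int(rng.integers(0, text_length - 4))
        admit(start, start + int(rng.integers(1, 5)),
              concept_ids[int(rng.integers(len(concept_ids)))])
    return predictions


def bruteforce_best_match(reference, predictions, ontology) -> float:
    """Exhaustive optimal one-to-one alignment: maximal total match mass.

    Independent oracle for the greedy aligner; enumerates all matchings
    over candidate pairs with textual overlap (feasible for <= 6 a side).
    """
    from paratag.evaluation import pair_similarity
    from paratag.core import spans_overlap

    pairs = {}
    for ri, r in enumerate(reference):
        for pi, p in enumerate(predictions):
            if spans_overlap(r.spans, p.spans):
                pairs[(ri, pi)] = pair_similarity(r, p, ontology).m

    def best(ri: int, used: frozenset) -> float:
        if ri == len(reference):
            return 0.0
        score = best(ri + 1, used)  # leave this reference unmatched
        for pi in range(len(predictions)):
            if pi not in used and (ri, pi) in pairs:
                score = max(
                    score,
                    pairs[(ri, pi)] + best(ri + 1, used | {pi}),
                )
        return score

    return best(0, frozenset())
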