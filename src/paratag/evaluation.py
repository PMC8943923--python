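"""Similarity-weighted scoring of concept annotations.

Predictions are aligned to reference annotations and tallied as
matches (M), substitutions (S), insertions (I) and deletions (D).  A
reference-prediction pair with textual overlap is scored by a fractional
similarity ``m = j * c`` where ``j`` is the character-level Jaccard
index of the two span sets and ``c`` the concept similarity: 1 for
identical IDs, otherwise the Jaccard index of the self-inclusive
``is_a`` ancestor sets in the ontology.  An accepted pair contributes
``m`` to the match count and ``1 - m`` to the substitution count, so
``m = 1`` exactly when spans and concept coincide.

Derived figures::

    P   = M / (M + S + I)          precision
    R   = M / (M + S + D)          recall
    F   = 2PR / (P + R)            F-score (0 when P = R = 0)
    SER = (S + I + D) / (M + S + D)   slot error rate

SER is 0 for a perfect system and may exceed 1; unlike F-score it
penalises insertions relative to the reference size, making it more
sensitive to false positives.  When the reference is empty but
predictions exist, SER has no denominator and is reported as undefined
(``None``), never as a number.

The unseen-concept protocol (:func:`filter_unseen`) restricts both
sides to annotations whose concept ID never occurs in the training
set, isolating a system's ability to predict novel concepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import Annotation, Ontology, Span, spans_overlap
from .errors import IntegrityError, ParameterError

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class EvalCounts:
    """Fractional match/substitution and integer insertion/deletion tallies.

    Conservation: ``M + S + D`` equals the number of reference
    annotations and ``M + S + I`` the number of predictions.
    """

    M: float
    S: float
    I: int
    D: int

    def __post_init__(self) -> None:
        if min(self.M, self.S, self.I, self.D) < -_EPS:
            raise ParameterError("negative evaluation counts")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.M + other.M, self.S + other.S, self.I + other.I, self.D + other.D
        )

    @property
    def n_reference(self) -> float:
        return self.M + self.S + self.D

    @property
    def n_predicted(self) -> float:
        return self.M + self.S + self.I


@dataclass(frozen=True)
class Metrics:
    """Precision, recall, F-score in [0, 1]; SER >= 0 or None (undefined)."""

    precision: float
    recall: float
    f_score: float
    ser: float | None


@dataclass(frozen=True)
class MatchSimilarity:
    """Components of the fractional similarity of one aligned pair."""

    j: float
    c: float

    @property
    def m(self) -> float:
        return self.j * self.c


def char_jaccard(a: Sequence[Span], b: Sequence[Span]) -> float:
    """Character-level Jaccard index of two span lists."""
    covered_a = {o for s in a for o in range(s.start, s.end)}
    covered_b = {o for s in b for o in range(s.start, s.end)}
    union = covered_a | covered_b
    if not union:
        return 0.0
    return len(covered_a & covered_b) / len(union)


def concept_similarity(id_a: str, id_b: str, ontology: Ontology) -> float:
    """Hierarchy-aware concept similarity in [0, 1].

    1 for identical IDs; otherwise the Jaccard index of the
    self-inclusive ancestor sets, so siblings share their common
    ancestry and concepts from disjoint trees score 0.  An ID missing
    from the ontology scores 0 with a logged warning.
    """
    if id_a == id_b:
        return 1.0
    missing = [cid for cid in (id_a, id_b) if cid not in ontology]
    if missing:
        logger.warning("concept(s) not in ontology: %s", ", ".join(missing))
        return 0.0
    anc_a = ontology.ancestors(id_a)
    anc_b = ontology.ancestors(id_b)
    return len(anc_a & anc_b) / len(anc_a | anc_b)


def pair_similarity(
    reference: Annotation, prediction: Annotation, ontology: Ontology
) -> MatchSimilarity:
    return MatchSimilarity(
        j=char_jaccard(reference.spans, prediction.spans),
        c=concept_similarity(reference.concept_id, prediction.concept_id, ontology),
    )


def _check_non_overlapping(annotations: Sequence[Annotation], side: str) -> None:
    ordered = sorted(annotations, key=lambda a: (a.start, a.end))
    for prev, nxt in zip(ordered, ordered[1:]):
        if spans_overlap(prev.spans, nxt.spans):
            raise IntegrityError(
                f"{side} annotations overlap ({prev.ann_id} vs {nxt.ann_id}): "
                "flatten before evaluating"
            )


def align_and_count(
    reference: Sequence[Annotation],
    predictions: Sequence[Annotation],
    ontology: Ontology,
) -> EvalCounts:
    """Greedy one-to-one alignment of predictions to references.

    Candidate pairs are all (reference, prediction) with textual overlap
    (``j > 0``; a wrong concept still pairs and counts as substitution).
    Pairs are ranked by ``m`` descending, then ``j`` descending, then
    reference start, then prediction start, and accepted greedily while
    both members are unused.  Unpaired references are deletions,
    unpaired predictions insertions.
    """
    _check_non_overlapping(reference, "reference")
    _check_non_overlapping(predictions, "prediction")
    candidates = []
    for ri, r in enumerate(reference):
        for pi, p in enumerate(predictions):
            if not spans_overlap(r.spans, p.spans):
                continue
            sim = pair_similarity(r, p, ontology)
            candidates.append((-sim.m, -sim.j, r.start, p.start, ri, pi))
    candidates.sort()
    used_r: set[int] = set()
    used_p: set[int] = set()
    M = S = 0.0
    for neg_m, _, _, _, ri, pi in candidates:
        if ri in used_r or pi in used_p:
            continue
        used_r.add(ri)
        used_p.add(pi)
        M += -neg_m
        S += 1 + neg_m
    return EvalCounts(
        M=M,
        S=S,
        I=len(predictions) - len(used_p),
        D=len(reference) - len(used_r),
    )


def compute_metrics(counts: EvalCounts) -> Metrics:
    """Precision, recall, F-score and slot error rate from the tallies.

    Conventions for empty sides: both empty is a perfect (vacuous)
    result; an empty reference with predictions leaves SER undefined.
    """
    n_ref = counts.n_reference
    n_pred = counts.n_predicted
    if n_ref < _EPS and n_pred < _EPS:
        return Metrics(1.0, 1.0, 1.0, 0.0)
    precision = counts.M / n_pred if n_pred > _EPS else 0.0
    recall = counts.M / n_ref if n_ref > _EPS else 0.0
    if precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    else:
        f_score = 0.0
    if n_ref > _EPS:
        ser: float | None = (counts.S + counts.I + counts.D) / n_ref
    else:
        ser = None
    return Metrics(precision, recall, f_score, ser)


def filter_unseen(
    annotations: Iterable[Annotation], training_ids: set[str] | frozenset[str]
) -> list[Annotation]:
    """Keep only annotations whose concept never occurs in training."""
    return [a for a in annotations if a.concept_id not in training_ids]


def evaluate(
    reference: Sequence[Annotation],
    predictions: Sequence[Annotation],
    ontology: Ontology,
    unseen_of: set[str] | frozenset[str] | None = None,
) -> tuple[Metrics, EvalCounts]:
    """Score predictions against a reference, optionally unseen-filtered.

    When ``unseen_of`` (the set of training concept IDs) is given, both
    sides are first restricted to concepts outside it.
    """
    if unseen_of is not None:
        reference = filter_unseen(reference, unseen_of)
        predictions = filter_unseen(predictions, unseen_of)
    counts = align_and_count(reference, predictions, ontology)
    return compute_metrics(counts), counts
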