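"""Seeded generators for ontologies and annotated corpora.

Every generator is a pure function of its parameters and a mandatory
seed, so all downstream experiments are reproducible without any
external download.  The corpora emulate the structural difficulties of
richly annotated biomedical text — discontinuous coordination mentions
("ES ... cells"), nested/overlapping annotations, ambiguous surface
forms, and a train/test split reserving a controllable fraction of
concepts for the test set only — without attempting statistical realism
of biomedical language.

:func:`fig2_fixture` is the minimal worked example of a discontinuous
annotation overlapping a contiguous one, on which the six
unification x unnesting combinations produce exactly four distinct
flattened outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Annotation, Concept, Document, Ontology, Span
from .errors import ParameterError

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: reserved words that never become synonyms or fillers
_COORDINATOR = "and"


@dataclass(frozen=True)
class CorpusSpec:
    """Knobs of the corpus generator; probabilities are per sentence."""

    n_docs: int = 4
    sentences_per_doc: int = 8
    mention_rate: float = 0.8
    p_discontinuous: float = 0.0
    p_overlap: float = 0.0
    p_ambiguous_surface: float = 0.0
    unseen_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.sentences_per_doc < 1:
            raise ParameterError("n_docs and sentences_per_doc must be >= 1")
        for name in ("mention_rate", "p_discontinuous", "p_overlap",
                     "p_ambiguous_surface"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if not 0.0 <= self.unseen_fraction < 1.0:
            raise ParameterError("unseen_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GeneratedCorpus:
    """Train/test documents with gold standoff annotations.

    ``extra_synonyms`` holds the surface forms invented during
    generation (coordination heads, nested terms, ambiguous strings) so
    that ``build_lexicon(ontology, extra_synonyms)`` covers every
    planted contiguous mention.  ``train_ids`` are the concepts
    available to an example-based tagger; ``unseen_ids`` occur only in
    the test gold.
    """

    train: tuple[tuple[Document, tuple[Annotation, ...]], ...]
    test: tuple[tuple[Document, tuple[Annotation, ...]], ...]
    extra_synonyms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    train_ids: frozenset[str] = frozenset()
    unseen_ids: frozenset[str] = frozenset()


class _Words:
    """Deterministic pronounceable-word factory with global uniqueness."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used = {_COORDINATOR}

    def fresh(self) -> str:
        for _ in range(10_000):
            n_syll = 2 + int(self.rng.integers(2))
            word = "".join(
                _CONSONANTS[int(self.rng.integers(len(_CONSONANTS)))]
                + _VOWELS[int(self.rng.integers(len(_VOWELS)))]
                for _ in range(n_syll)
            )
            if word not in self.used:
                self.used.add(word)
                return word
        raise ParameterError("word inventory exhausted")  # pragma: no cover


def gen_ontology(
    n_concepts: int,
    max_parents: int = 2,
    n_synonyms: int = 2,
    seed: int = 0,
    p_ambiguous: float = 0.0,
) -> Ontology:
    """Rooted acyclic ``is_a`` graph with synthetic names and synonyms.

    Concept IDs are ``SYN:0000001``...; every non-root concept has 1 to
    ``max_parents`` parents among earlier concepts, so a topological
    order exists by construction.  Each concept gets a unique
    single-word name, one two-word synonym and further single-word
    synonyms; with probability ``p_ambiguous`` a synonym is copied from
    an earlier concept, creating a deliberately ambiguous surface form.
    """
    if n_concepts < 1:
        raise ParameterError("n_concepts must be >= 1")
    if max_parents < 1 or n_synonyms < 0:
        raise ParameterError("max_parents >= 1 and n_synonyms >= 0 required")
    rng = np.random.default_rng(seed)
    words = _Words(rng)
    concepts: dict[str, Concept] = {}
    ids: list[str] = []
    synonym_pool: list[str] = []
    for i in range(1, n_concepts + 1):
        cid = f"SYN:{i:07d}"
        name = words.fresh()
        synonyms = {name, f"{words.fresh()} {words.fresh()}"}
        for _ in range(n_synonyms):
            if synonym_pool and rng.random() < p_ambiguous:
                synonyms.add(synonym_pool[int(rng.integers(len(synonym_pool)))])
            else:
                synonyms.add(words.fresh())
        if ids:
            k = 1 + int(rng.integers(min(max_parents, len(ids))))
            parent_idx = rng.choice(len(ids), size=k, replace=False)
            parents = frozenset(ids[int(j)] for j in parent_idx)
        else:
            parents = frozenset()
        concepts[cid] = Concept(cid, name, frozenset(synonyms), parents)
        ids.append(cid)
        synonym_pool.extend(synonyms)
    return Ontology(concepts)


class _DocBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0

    def add(self, chunk: str) -> Span:
        if self.parts:
            self.parts.append(" ")
            self.length += 1
        start = self.length
        self.parts.append(chunk)
        self.length += len(chunk)
        return Span(start, self.length)

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _plant_sentence(
    builder: _DocBuilder,
    rng: np.random.Generator,
    words: _Words,
    fillers: Sequence[str],
    ontology: Ontology,
    pool: Sequence[str],
    spec: CorpusSpec,
    extras: dict[str, set[str]],
    anns: list[tuple[str, tuple[Span, ...], str]],
    forced_concept: str | None = None,
) -> None:
    """Append one sentence, optionally planting a mention structure."""

    def fill(k: int) -> None:
        for _ in range(k):
            builder.add(fillers[int(rng.integers(len(fillers)))])

    fill(1 + int(rng.integers(3)))
    plant = forced_concept is not None or rng.random() < spec.mention_rate
    if plant:
        draw = rng.random()
        if forced_concept is not None:
            surface = _pick_surface(rng, ontology, forced_concept)
            span = builder.add(surface)
            anns.append((forced_concept, (span,), surface))
        elif draw < spec.p_discontinuous and len(pool) >= 2:
            ca, cb = _pick_two(rng, pool)
            a1, b1, head = words.fresh(), words.fresh(), words.fresh()
            span_a1 = builder.add(a1)
            builder.add(_COORDINATOR)
            span_b1 = builder.add(b1)
            span_head = builder.add(head)
            extras.setdefault(f"{a1} {head}", set()).add(ca)
            extras.setdefault(f"{b1} {head}", set()).add(cb)
            anns.append((ca, (span_a1, span_head), f"{a1} {head}"))
            anns.append((cb, (Span(span_b1.start, span_head.end),), f"{b1} {head}"))
        elif draw < spec.p_discontinuous + spec.p_overlap and len(pool) >= 2:
            cc, cd = _pick_two(rng, pool)
            w1, w2 = words.fresh(), words.fresh()
            span_w1 = builder.add(w1)
            span_w2 = builder.add(w2)
            extras.setdefault(f"{w1} {w2}", set()).add(cc)
            extras.setdefault(w2, set()).add(cd)
            anns.append((cc, (Span(span_w1.start, span_w2.end),), f"{w1} {w2}"))
            anns.append((cd, (span_w2,), w2))
        elif (draw < spec.p_discontinuous + spec.p_overlap
              + spec.p_ambiguous_surface and len(pool) >= 2):
            ce, cf = _pick_two(rng, pool)
            shared = words.fresh()
            span = builder.add(shared)
            extras.setdefault(shared, set()).update({ce, cf})
            anns.append((ce, (span,), shared))
        else:
            concept = pool[int(rng.integers(len(pool)))]
            surface = _pick_surface(rng, ontology, concept)
            span = builder.add(surface)
            anns.append((concept, (span,), surface))
    fill(1 + int(rng.integers(3)))
    builder.add(".")


def _pick_surface(rng: np.random.Generator, ontology: Ontology, cid: str) -> str:
    options = sorted(ontology[cid].synonyms)
    return options[int(rng.integers(len(options)))]


def _pick_two(rng: np.random.Generator, pool: Sequence[str]) -> tuple[str, str]:
    idx = rng.choice(len(pool), size=2, replace=False)
    return pool[int(idx[0])], pool[int(idx[1])]


def _build_doc(
    doc_id: str,
    sentences: int,
    rng: np.random.Generator,
    words: _Words,
    fillers: Sequence[str],
    ontology: Ontology,
    pool: Sequence[str],
    spec: CorpusSpec,
    extras: dict[str, set[str]],
    forced_concepts: Sequence[str] = (),
) -> tuple[Document, tuple[Annotation, ...]]:
    builder = _DocBuilder()
    raw: list[tuple[str, tuple[Span, ...], str]] = []
    forced = list(forced_concepts)
    for s in range(max(sentences, len(forced))):
        _plant_sentence(
            builder, rng, words, fillers, ontology, pool, spec, extras, raw,
            forced_concept=forced[s] if s < len(forced) else None,
        )
    document = Document(doc_id, builder.text)
    annotations = tuple(
        Annotation(f"T{n}", cid, spans, text, document=document)
        for n, (cid, spans, text) in enumerate(raw, start=1)
    )
    return document, annotations


def gen_corpus(
    ontology: Ontology, spec: CorpusSpec
) -> GeneratedCorpus:
    """Generate a seeded train/test corpus with planted mentions.

    Exactly ``ceil(unseen_fraction * n_concepts)`` concepts are reserved
    for the test gold: they never occur in training annotations, and
    each of them occurs at least once in the test set.  Every remaining
    concept occurs at least once in the training gold, so the test-only
    concept set is exactly the reserved one.
    """
    rng = np.random.default_rng(spec.seed)
    words = _Words(rng)
    # keep generated sentence words disjoint from ontology terms
    for cid in ontology:
        for term in ontology[cid].synonyms | {ontology[cid].name}:
            words.used.update(term.split())
    fillers = [words.fresh() for _ in range(12)]

    ids = sorted(ontology.ids)
    rng.shuffle(ids)
    n_unseen = math.ceil(spec.unseen_fraction * len(ids))
    if len(ids) - n_unseen < 1:
        raise ParameterError(
            f"unseen_fraction={spec.unseen_fraction} leaves no concept "
            "for the training set"
        )
    unseen = ids[:n_unseen]
    seen = ids[n_unseen:]

    extras: dict[str, set[str]] = {}
    train = []
    train_used: set[str] = set()
    for d in range(spec.n_docs):
        doc, anns = _build_doc(
            f"train{d + 1:04d}", spec.sentences_per_doc, rng, words, fillers,
            ontology, seen, spec, extras,
        )
        train.append((doc, anns))
        train_used.update(a.concept_id for a in anns)
    missing_seen = sorted(set(seen) - train_used)
    if missing_seen:
        train.append(
            _build_doc(
                "train_coverage", len(missing_seen), rng, words, fillers,
                ontology, seen, spec, extras, forced_concepts=missing_seen,
            )
        )

    test = []
    test_used: set[str] = set()
    n_test_docs = max(1, math.ceil(spec.n_docs / 2))
    for d in range(n_test_docs):
        doc, anns = _build_doc(
            f"test{d + 1:04d}", spec.sentences_per_doc, rng, words, fillers,
            ontology, ids, spec, extras,
        )
        test.append((doc, anns))
        test_used.update(a.concept_id for a in anns)
    missing_unseen = sorted(set(unseen) - test_used)
    if missing_unseen:
        test.append(
            _build_doc(
                "test_coverage", len(missing_unseen), rng, words, fillers,
                ontology, ids, spec, extras, forced_concepts=missing_unseen,
            )
        )

    return GeneratedCorpus(
        train=tuple(train),
        test=tuple(test),
        extra_synonyms={k: tuple(sorted(v)) for k, v in sorted(extras.items())},
        train_ids=frozenset(seen),
        unseen_ids=frozenset(unseen),
    )


def fig2_fixture() -> tuple[Document, list[Annotation]]:
    """A discontinuous mention overlapping a contiguous one.

    ``"ES and somatic cells"`` carries a discontinuous annotation over
    the fragments "ES" and "cells" and a contiguous annotation over
    "somatic cells".  The six unification x unnesting combinations
    flatten it to four distinct outcomes, three of which have lost one
    of the two annotations entirely.
    """
    document = Document("fig2", "ES and somatic cells")
    return document, [
        Annotation("T1", "CL:0000001", [(0, 2), (15, 20)], document=document),
        Annotation("T2", "CL:0000002", [(7, 20)], document=document),
    ]
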