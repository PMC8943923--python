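"""Prediction channels at desk scale.

Three sources of token-level predictions feed harmonisation:

* a dictionary tagger that matches ontology terms (names and synonyms)
  in running text by exact lookup over normalised token n-grams — the
  knowledge-based, high-recall channel;
* a memorisation tagger that memorises the normalised surface forms of
  training annotations and re-tags them greedily at prediction time — a
  minimal example-based stand-in for a trained sequence classifier that
  reproduces, by construction, its defining structural constraint: it
  can only ever predict concept IDs seen during training;
* a seeded corruption oracle that perturbs gold label sequences to
  produce controlled disagreement between the span and ID channels.

Real classifier output in the CoNLL dialect can be imported via
:func:`paratag.io.read_conll` and harmonised in exactly the same way.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    NIL,
    OUTSIDE,
    Annotation,
    Document,
    LabelledToken,
    Ontology,
    Span,
    StrategyConfig,
    Token,
)
from .errors import IntegrityError, ParameterError
from .flattening import FlatAnnotation, decode_units, flatten_annotations, tokenize


def normalise(term: str) -> str:
    """Canonical surface form: lower-case, punctuation to spaces,
    whitespace collapsed.  ``"X-Gal"`` becomes ``"x gal"``."""
    chars = [ch.lower() if ch.isalnum() else " " for ch in term]
    return " ".join("".join(chars).split())


def _term_token_count(term: str) -> int:
    return len(tokenize(Document("t", term)))


@dataclass(frozen=True)
class Lexicon:
    """Normalised term string -> candidate concept IDs.

    ``max_term_tokens`` is the token count of the longest indexed term
    (counted with the package tokeniser on the raw term), bounding the
    n-gram enumeration at match time.
    """

    entries: Mapping[str, frozenset[str]]
    max_term_tokens: int


def build_lexicon(
    ontology: Ontology,
    extra_synonyms: Mapping[str, str | Iterable[str]] | None = None,
) -> Lexicon:
    """Index every concept name and synonym, plus manual extra synonyms.

    Extra synonyms map a term to a concept ID (or several); referencing
    a concept absent from the ontology raises :class:`IntegrityError`.
    """
    entries: dict[str, set[str]] = {}
    max_tokens = 0

    def add(term: str, concept_id: str) -> None:
        nonlocal max_tokens
        key = normalise(term)
        if not key:
            return
        entries.setdefault(key, set()).add(concept_id)
        max_tokens = max(max_tokens, _term_token_count(term))

    for cid in ontology:
        concept = ontology[cid]
        for term in concept.synonyms | {concept.name}:
            add(term, cid)
    for term, cids in (extra_synonyms or {}).items():
        if isinstance(cids, str):
            cids = [cids]
        for cid in cids:
            if cid not in ontology:
                raise IntegrityError(
                    f"extra synonym {term!r} references unknown concept {cid}"
                )
            add(term, cid)
    return Lexicon(
        {k: frozenset(v) for k, v in entries.items()}, max_tokens
    )


def dict_tag(
    document: Document, tokens: Sequence[Token], lexicon: Lexicon
) -> tuple[list[FlatAnnotation], list[frozenset[str]]]:
    """Exact dictionary matching over normalised token n-grams.

    Every n-gram (n up to ``max_term_tokens``) whose normalised document
    substring is an indexed term is reported; overlapping and nested
    matches are all kept.  Returns entity-level matches (one
    :class:`FlatAnnotation` per candidate concept ID) and the per-token
    dictionary feature: the union of IDs of all matches covering the
    token.
    """
    matches: list[FlatAnnotation] = []
    features: list[set[str]] = [set() for _ in tokens]
    for i in range(len(tokens)):
        for n in range(1, lexicon.max_term_tokens + 1):
            j = i + n - 1
            if j >= len(tokens):
                break
            span = Span(tokens[i].span.start, tokens[j].span.end)
            ids = lexicon.entries.get(normalise(document.text[span.start : span.end]))
            if not ids:
                continue
            for cid in sorted(ids):
                matches.append(FlatAnnotation(cid, span))
            for k in range(i, j + 1):
                features[k] |= ids
    return matches, [frozenset(f) for f in features]


@dataclass(frozen=True)
class MemorisationModel:
    """Normalised training surface -> concept-ID frequency table."""

    surfaces: Mapping[str, Mapping[str, int]]
    label_set: frozenset[str]
    max_surface_tokens: int
    channel: str = "id"


def train_memorisation(
    corpus: Sequence[tuple[Document, Sequence[Annotation]]],
    channel: str = "id",
    config: StrategyConfig | None = None,
) -> MemorisationModel:
    """Memorise flattened gold annotations as surface -> ID counts.

    Gold annotations are flattened with ``config`` (default strategy
    pair) so the model sees exactly what a CoNLL-trained classifier
    would see; its label set is therefore limited to training IDs.
    """
    if channel not in ("span", "id"):
        raise ParameterError(f"unknown channel {channel!r}")
    config = config or StrategyConfig()
    table: dict[str, Counter] = {}
    max_tokens = 0
    for document, gold in corpus:
        tokens = tokenize(document)
        for flat in flatten_annotations(document, gold, config, tokens):
            surface = document.text[flat.start : flat.end]
            key = normalise(surface)
            if not key:
                continue
            table.setdefault(key, Counter())[flat.concept_id] += 1
            n_tok = sum(1 for t in tokens if t.span.overlaps(flat.span))
            max_tokens = max(max_tokens, n_tok)
    label_set = frozenset(cid for counts in table.values() for cid in counts)
    return MemorisationModel(
        {k: dict(v) for k, v in table.items()}, label_set, max_tokens, channel
    )


def predict_memorisation(
    model: MemorisationModel, document: Document, tokens: Sequence[Token]
) -> list[LabelledToken]:
    """Greedy longest-match left-to-right re-tagging of known surfaces.

    A matched n-gram is tagged ``S`` or ``B``...``E`` on the span
    channel and labelled with the surface's most frequent concept ID
    (frequency ties broken by the lexically lowest ID).  The dictionary
    channel is left empty.  Every emitted ID is in ``model.label_set``.
    """
    span_tags = [OUTSIDE] * len(tokens)
    id_tags = [NIL] * len(tokens)
    i = 0
    while i < len(tokens):
        matched = 0
        match_id = NIL
        limit = min(model.max_surface_tokens, len(tokens) - i)
        for n in range(limit, 0, -1):
            span = Span(tokens[i].span.start, tokens[i + n - 1].span.end)
            counts = model.surfaces.get(
                normalise(document.text[span.start : span.end])
            )
            if counts:
                matched = n
                match_id = min(counts, key=lambda c: (-counts[c], c))
                break
        if matched == 0:
            i += 1
            continue
        if matched == 1:
            span_tags[i] = "S"
        else:
            span_tags[i] = "B"
            for k in range(i + 1, i + matched - 1):
                span_tags[k] = "I"
            span_tags[i + matched - 1] = "E"
        for k in range(i, i + matched):
            id_tags[k] = match_id
        i += matched
    return [
        LabelledToken(token=t, span_tag=st, id_tag=it)
        for t, st, it in zip(tokens, span_tags, id_tags)
    ]


def corrupt_labels(
    labelled: Sequence[LabelledToken],
    p_span_flip: float = 0.0,
    p_id_swap: float = 0.0,
    p_drop: float = 0.0,
    seed: int = 0,
    label_set: Iterable[str] | None = None,
) -> list[LabelledToken]:
    """Seeded per-entity corruption of the span and ID channels.

    For each gold entity, independently per channel: with ``p_drop`` the
    entity vanishes from that channel (tags to ``O`` / IDs to ``NIL``);
    with ``p_span_flip`` one boundary of the span-channel entity moves
    by one token where possible; with ``p_id_swap`` the ID-channel
    entity's concept is replaced by a uniformly drawn different ID from
    the label set.  Deterministic for a given (input, seed); dictionary
    features are untouched.
    """
    for name, p in (("p_span_flip", p_span_flip), ("p_id_swap", p_id_swap),
                    ("p_drop", p_drop)):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name}={p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    units = decode_units(labelled, repair=False)
    span_tags = [lt.span_tag for lt in labelled]
    id_tags = [lt.id_tag for lt in labelled]
    ids = sorted(set(label_set) if label_set is not None
                 else {cid for _, _, cid in units})
    entity_tokens = set()
    for first, last, _ in units:
        entity_tokens.update(range(first, last + 1))

    for first, last, cid in units:
        # span channel
        if rng.random() < p_drop:
            for k in range(first, last + 1):
                span_tags[k] = OUTSIDE
        elif rng.random() < p_span_flip:
            moves = []
            if first - 1 >= 0 and first - 1 not in entity_tokens:
                moves.append(("start", first - 1))
            if last + 1 < len(labelled) and last + 1 not in entity_tokens:
                moves.append(("end", last + 1))
            if last > first:
                moves.append(("start", first + 1))
                moves.append(("end", last - 1))
            if moves:
                which, new = moves[int(rng.integers(len(moves)))]
                new_first, new_last = first, last
                if which == "start":
                    span_tags[first] = OUTSIDE
                    new_first = new
                else:
                    span_tags[last] = OUTSIDE
                    new_last = new
                for k in range(new_first, new_last + 1):
                    span_tags[k] = "I"
                span_tags[new_first] = "B" if new_last > new_first else "S"
                if new_last > new_first:
                    span_tags[new_last] = "E"
        # ID channel, independently
        if rng.random() < p_drop:
            for k in range(first, last + 1):
                id_tags[k] = NIL
        elif rng.random() < p_id_swap:
            others = [c for c in ids if c != cid]
            if others:
                swapped = others[int(rng.integers(len(others)))]
                for k in range(first, last + 1):
                    id_tags[k] = swapped
    return [
        lt.replace(span_tag=st, id_tag=it)
        for lt, st, it in zip(labelled, span_tags, id_tags)
    ]
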