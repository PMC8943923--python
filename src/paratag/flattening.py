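"""Lossy conversion between standoff annotations and token label sequences.

A token-per-row (CoNLL-style) representation forces exactly one label
onto each token, so discontinuous, overlapping and sub-word annotations
must be simplified before encoding:

1. *unification* collapses a discontinuous annotation to one contiguous
   span (``first-span`` keeps the first fragment, ``last-span`` the
   last, ``full-span`` stretches from the first fragment's start to the
   last fragment's end);
2. *snapping* extends sub-word spans to whole-token boundaries;
3. *unnesting* removes overlaps by greedy preference (``keep-longer`` or
   ``keep-shorter``).

Snapping can create new overlaps, so unnesting runs last.  The surviving
contiguous, token-aligned annotations are then encoded as parallel IOBES
span tags and concept-ID tags; :func:`decode_entities` is the inverse,
with optional repair rules for ill-formed predicted sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Sequence

from .core import (
    NIL,
    OUTSIDE,
    Annotation,
    Document,
    LabelledToken,
    Span,
    StrategyConfig,
    Token,
    Unification,
    Unnesting,
)
from .errors import ConsistencyError, DegenerateSpanError

# Maximal runs of Unicode letters/digits, or any single non-space
# character (underscore counts as punctuation, like a hyphen).
_TOKEN_RE = re.compile(r"[^\W_]+|\S", re.UNICODE)


@dataclass(frozen=True)
class FlatAnnotation:
    """A contiguous (single-span) annotation, as required by token labels."""

    concept_id: str
    span: Span
    ann_id: str = "?"

    @property
    def start(self) -> int:
        return self.span.start

    @property
    def end(self) -> int:
        return self.span.end


def tokenize(document: Document) -> list[Token]:
    """Deterministic, language-independent tokenisation.

    Tokens are maximal runs of letters and digits, or single punctuation
    characters; every non-space character belongs to exactly one token.
    ``"Ephrin-B1"`` yields ``["Ephrin", "-", "B1"]``.
    """
    return [
        Token(m.group(), Span(m.start(), m.end()))
        for m in _TOKEN_RE.finditer(document.text)
    ]


def unify_discontinuous(
    annotation: Annotation, strategy: Unification | str
) -> FlatAnnotation:
    """Collapse a discontinuous annotation to a single contiguous span.

    Contiguous annotations pass through unchanged under every strategy.
    """
    strategy = Unification(strategy)
    spans = annotation.spans
    if strategy is Unification.FIRST_SPAN:
        span = spans[0]
    elif strategy is Unification.LAST_SPAN:
        span = spans[-1]
    else:  # full-span
        span = Span(spans[0].start, spans[-1].end)
    return FlatAnnotation(annotation.concept_id, span, annotation.ann_id)


def unnest_overlaps(
    annotations: Sequence[FlatAnnotation], strategy: Unnesting | str
) -> list[FlatAnnotation]:
    """Greedily remove overlaps, preferring longer or shorter spans.

    Candidates are ranked by length (descending for keep-longer,
    ascending for keep-shorter), then start offset, then concept ID, and
    accepted whenever they overlap no previously accepted annotation.
    The result is pairwise non-overlapping and returned in text order.
    """
    strategy = Unnesting(strategy)
    descending = strategy is Unnesting.KEEP_LONGER
    ranked = sorted(
        annotations,
        key=lambda a: (
            -len(a.span) if descending else len(a.span),
            a.start,
            a.concept_id,
        ),
    )
    accepted: list[FlatAnnotation] = []
    for cand in ranked:
        if not any(cand.span.overlaps(a.span) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda a: (a.start, a.end, a.concept_id))
    return accepted


def snap_to_token_boundaries(
    flat: FlatAnnotation, tokens: Sequence[Token]
) -> FlatAnnotation:
    """Extend a (possibly sub-word) span to whole-token boundaries.

    The span grows to the smallest token-aligned interval covering every
    token it overlaps; token-aligned spans are left unchanged
    (idempotence).  A span overlapping no token at all cannot be
    represented in the token sequence.
    """
    covered = [t for t in tokens if t.span.overlaps(flat.span)]
    if not covered:
        raise DegenerateSpanError(
            f"annotation {flat.ann_id} ({flat.concept_id}) at "
            f"({flat.start}, {flat.end}) overlaps no token"
        )
    return replace(flat, span=Span(covered[0].span.start, covered[-1].span.end))


def flatten_annotations(
    document: Document,
    gold: Sequence[Annotation],
    config: StrategyConfig,
    tokens: Sequence[Token] | None = None,
) -> list[FlatAnnotation]:
    """Full simplification pipeline: unify, snap, unnest."""
    if tokens is None:
        tokens = tokenize(document)
    flats = [unify_discontinuous(a, config.unification) for a in gold]
    flats = [snap_to_token_boundaries(f, tokens) for f in flats]
    return unnest_overlaps(flats, config.unnesting)


def encode_labels(
    document: Document,
    gold: Sequence[Annotation],
    config: StrategyConfig,
    tokens: Sequence[Token] | None = None,
) -> list[LabelledToken]:
    """Flatten ``gold`` and encode it as IOBES + concept-ID token labels.

    A single-token entity is tagged ``S``; a multi-token entity ``B``,
    ``I``..., ``E``.  Every entity token carries the entity's concept ID
    on the ID channel; all other tokens are ``O``/``NIL``.  The
    dictionary channel is left empty.
    """
    if tokens is None:
        tokens = tokenize(document)
    flats = flatten_annotations(document, gold, config, tokens)
    span_tags = [OUTSIDE] * len(tokens)
    id_tags = [NIL] * len(tokens)
    for flat in flats:
        idx = [i for i, t in enumerate(tokens) if t.span.overlaps(flat.span)]
        if len(idx) == 1:
            span_tags[idx[0]] = "S"
        else:
            span_tags[idx[0]] = "B"
            for i in idx[1:-1]:
                span_tags[i] = "I"
            span_tags[idx[-1]] = "E"
        for i in idx:
            id_tags[i] = flat.concept_id
    return [
        LabelledToken(token=t, span_tag=st, id_tag=it)
        for t, st, it in zip(tokens, span_tags, id_tags)
    ]


def decode_units(
    labelled: Sequence[LabelledToken],
    repair: bool = False,
    id_backoff: bool = False,
    use_ids: bool = True,
) -> list[tuple[int, int, str]]:
    """Decode token labels into units ``(first_index, last_index, id)``.

    With ``repair=False`` the sequence must be well-formed: ``S`` stands
    alone, ``B`` ... ``E`` carries one uniform non-NIL concept ID, and a
    token is ``O`` exactly when its ID is ``NIL``.  Violations raise
    :class:`ConsistencyError` naming the token index.

    With ``repair=True`` ill-formed sequences are normalised first:

    * R1 — ``I`` or ``E`` with no open entity acts as ``B``;
    * R2 — an open entity interrupted by ``O``, ``B`` or ``S`` closes at
      the previous token;
    * R3 — an ID change inside an open entity closes it before the
      changed token;
    * R4 — a non-NIL ID on an ``O`` token opens a unit only when
      ``id_backoff`` is enabled (harmonisation uses this; plain decoding
      does not).

    With ``use_ids=False`` (repair mode only) the ID channel is ignored
    entirely: R3 never fires and units are reported with concept ID
    ``NIL``, leaving identification to the caller — this is how the
    spans-only harmonisation strategy extracts boundaries.  Otherwise,
    units whose concept ID is ``NIL`` (span tags without any ID) are
    dropped in repair mode; strict mode rejects them.
    """
    units: list[tuple[int, int, str]] = []
    open_start: int | None = None
    open_id: str = NIL

    if not repair:
        _decode_strict(labelled, units)
        return units

    def close(start: int, last: int, concept_id: str) -> None:
        if concept_id != NIL or not use_ids:
            units.append((start, last, concept_id))

    for i, lt in enumerate(labelled):
        tag = lt.span_tag
        cid = lt.id_tag if use_ids else NIL
        if tag == OUTSIDE:
            if open_start is not None:
                close(open_start, i - 1, open_id)  # R2
                open_start = None
            if cid != NIL and id_backoff:  # R4
                units.append((i, i, cid))
            continue
        if tag == "S":
            if open_start is not None:
                close(open_start, i - 1, open_id)  # R2
                open_start = None
            close(i, i, cid)
            continue
        if tag == "B":
            if open_start is not None:
                close(open_start, i - 1, open_id)  # R2
            open_start, open_id = i, cid
            continue
        # I or E
        if open_start is None:
            open_start, open_id = i, cid  # R1
        elif use_ids and cid != open_id:
            close(open_start, i - 1, open_id)  # R3
            open_start, open_id = i, cid
        if tag == "E":
            close(open_start, i, open_id)
            open_start = None
    if open_start is not None:
        close(open_start, len(labelled) - 1, open_id)  # R2
    return units


def _decode_strict(
    labelled: Sequence[LabelledToken], units: list[tuple[int, int, str]]
) -> None:
    open_start: int | None = None
    open_id: str = NIL
    for i, lt in enumerate(labelled):
        tag, cid = lt.span_tag, lt.id_tag
        if (tag == OUTSIDE) != (cid == NIL):
            raise ConsistencyError(
                f"token {i}: span tag {tag} inconsistent with ID {cid}"
            )
        if tag == OUTSIDE:
            if open_start is not None:
                raise ConsistencyError(f"token {i}: entity interrupted by O")
            continue
        if tag == "S":
            if open_start is not None:
                raise ConsistencyError(f"token {i}: S inside an open entity")
            units.append((i, i, cid))
        elif tag == "B":
            if open_start is not None:
                raise ConsistencyError(f"token {i}: B inside an open entity")
            open_start, open_id = i, cid
        elif tag in ("I", "E"):
            if open_start is None:
                raise ConsistencyError(f"token {i}: {tag} with no open entity")
            if cid != open_id:
                raise ConsistencyError(
                    f"token {i}: ID {cid} differs from entity ID {open_id}"
                )
            if tag == "E":
                units.append((open_start, i, cid))
                open_start = None
    if open_start is not None:
        raise ConsistencyError(
            f"token {open_start}: entity opened with B but never closed"
        )


def decode_entities(
    labelled: Sequence[LabelledToken],
    repair: bool = False,
    document: Document | None = None,
    id_backoff: bool = False,
) -> list[Annotation]:
    """Inverse of :func:`encode_labels`: token labels back to standoff.

    Each decoded unit becomes one contiguous annotation spanning from
    its first token's start to its last token's end.  When ``document``
    is given the annotation text is sliced from it; otherwise token
    surfaces are joined with single spaces.
    """
    units = decode_units(labelled, repair=repair, id_backoff=id_backoff)
    annotations = []
    for n, (first, last, cid) in enumerate(units, start=1):
        span = Span(labelled[first].token.span.start, labelled[last].token.span.end)
        if document is not None:
            text = document.text[span.start : span.end]
        else:
            text = " ".join(lt.token.surface for lt in labelled[first : last + 1])
        annotations.append(Annotation(f"T{n}", cid, [span], text))
    return annotations
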