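"""Merging the span, ID and dictionary channels into one annotation set.

The span tagger and the ID tagger are trained (or corrupted) in
parallel, so their predictions are not guaranteed to agree: a token may
carry a relevant IOBES tag with a NIL concept, or a concept ID under an
O tag, and the dictionary feature may or may not support either.  Each
channel being binary relevant/irrelevant for a token gives 2x2x2 = 8
prediction patterns (:func:`relevance_pattern`).

Four harmonisation strategies with a fixed bias resolve the conflicts:

* ``spans-only`` — trust the IOBES channel for boundaries, ignore the
  ID channel entirely; concept IDs come from overlapping dictionary
  matches (ranked by character Jaccard, ties to the lexically lowest
  ID).  Since a concept label is always required, span entities with no
  supporting dictionary match are dropped.
* ``ids-only`` — trust the ID channel: maximal runs of one non-NIL
  concept become annotations; span tags and dictionary are ignored.
* ``spans-first`` — apply spans-only, then back off to ids-only on the
  tokens it left unclaimed.
* ``ids-first`` — apply ids-only, then fill unclaimed tokens from the
  span channel; truncated span remnants must re-pass the
  dictionary-support test.

Backoff works at token granularity with entity-level ID assignment: a
backoff entity is truncated to its maximal contiguous sub-runs of
unclaimed tokens, keeping its concept ID; empty remnants disappear.
The output of every strategy is pairwise non-overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import (
    NIL,
    OUTSIDE,
    Annotation,
    Document,
    Harmonisation,
    LabelledToken,
    Span,
)
from .errors import ConfigurationError
from .evaluation import char_jaccard
from .flattening import FlatAnnotation, decode_units


@dataclass(frozen=True)
class HarmonisationInput:
    """Aligned token channels plus entity-level dictionary matches."""

    tokens: Sequence[LabelledToken]
    dict_matches: Sequence[FlatAnnotation] = ()
    document: Document | None = None


def relevance_pattern(token: LabelledToken) -> tuple[int, int, int]:
    """(span relevant, ID relevant, dictionary relevant) for one token."""
    return (
        int(token.span_tag != OUTSIDE),
        int(token.id_tag != NIL),
        int(len(token.dict_ids) > 0),
    )


def matches_from_features(tokens: Sequence[LabelledToken]) -> list[FlatAnnotation]:
    """Reconstruct entity-level dictionary matches from per-token features.

    For each concept ID, every maximal run of consecutive tokens whose
    dictionary feature contains the ID becomes one match.  Exact for
    non-adjacent matches; adjacent same-ID matches merge (information
    the per-token features no longer carry).
    """
    ids = sorted({cid for lt in tokens for cid in lt.dict_ids})
    matches = []
    for cid in ids:
        run_start: int | None = None
        for i, lt in enumerate(list(tokens) + [None]):  # sentinel flushes
            inside = lt is not None and cid in lt.dict_ids
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                matches.append(
                    FlatAnnotation(
                        cid,
                        Span(
                            tokens[run_start].token.span.start,
                            tokens[i - 1].token.span.end,
                        ),
                    )
                )
                run_start = None
    matches.sort(key=lambda m: (m.start, m.end, m.concept_id))
    return matches


# ---------------------------------------------------------------------------
# unit-level machinery (token index ranges)

_Unit = tuple[int, int, str]  # first token index, last token index, concept ID


def _unit_span(tokens: Sequence[LabelledToken], first: int, last: int) -> Span:
    return Span(tokens[first].token.span.start, tokens[last].token.span.end)


def _resolve_from_dict(
    tokens: Sequence[LabelledToken],
    first: int,
    last: int,
    dict_matches: Sequence[FlatAnnotation],
) -> str | None:
    """Best dictionary concept for a token range, or None if unsupported.

    Candidates are dictionary matches overlapping the range, ranked by
    character Jaccard with it (descending); ties take the lexically
    lowest concept ID.
    """
    span = _unit_span(tokens, first, last)
    best: tuple[float, str] | None = None
    for m in dict_matches:
        if not m.span.overlaps(span):
            continue
        j = char_jaccard([span], [m.span])
        if best is None or (-j, m.concept_id) < (-best[0], best[1]):
            best = (j, m.concept_id)
    return best[1] if best else None


def _spans_only_units(inp: HarmonisationInput) -> list[_Unit]:
    units = []
    for first, last, _ in decode_units(inp.tokens, repair=True, use_ids=False):
        cid = _resolve_from_dict(inp.tokens, first, last, inp.dict_matches)
        if cid is not None:
            units.append((first, last, cid))
    return units


def _ids_only_units(inp: HarmonisationInput) -> list[_Unit]:
    units = []
    run_start: int | None = None
    current = NIL
    for i, lt in enumerate(list(inp.tokens) + [None]):
        cid = NIL if lt is None else lt.id_tag
        if cid != current:
            if run_start is not None and current != NIL:
                units.append((run_start, i - 1, current))
            run_start, current = i, cid
    return units


def _truncate_to_unclaimed(
    units: Sequence[_Unit], claimed: set[int]
) -> list[_Unit]:
    """Split units into maximal contiguous sub-runs of unclaimed tokens."""
    remnants = []
    for first, last, cid in units:
        start: int | None = None
        for i in range(first, last + 2):
            free = i <= last and i not in claimed
            if free and start is None:
                start = i
            elif not free and start is not None:
                remnants.append((start, i - 1, cid))
                start = None
    return remnants


def _to_annotations(
    inp: HarmonisationInput, units: Sequence[_Unit]
) -> list[Annotation]:
    ordered = sorted(units, key=lambda u: (u[0], u[1], u[2]))
    annotations = []
    for n, (first, last, cid) in enumerate(ordered, start=1):
        span = _unit_span(inp.tokens, first, last)
        if inp.document is not None:
            text = inp.document.text[span.start : span.end]
        else:
            text = " ".join(
                lt.token.surface for lt in inp.tokens[first : last + 1]
            )
        annotations.append(Annotation(f"T{n}", cid, [span], text))
    return annotations


# ---------------------------------------------------------------------------
# strategies


def spans_only(inp: HarmonisationInput) -> list[Annotation]:
    """Entity boundaries from the IOBES channel, IDs from the dictionary."""
    return _to_annotations(inp, _spans_only_units(inp))


def ids_only(inp: HarmonisationInput) -> list[Annotation]:
    """Maximal same-ID runs of the ID channel; span tags overridden."""
    return _to_annotations(inp, _ids_only_units(inp))


def harmonise(
    inp: HarmonisationInput, strategy: Harmonisation | str
) -> list[Annotation]:
    """Merge the three channels under the chosen strategy."""
    try:
        strategy = Harmonisation(strategy)
    except ValueError:
        raise ConfigurationError(f"unknown harmonisation strategy {strategy!r}")
    if strategy is Harmonisation.SPANS_ONLY:
        return spans_only(inp)
    if strategy is Harmonisation.IDS_ONLY:
        return ids_only(inp)
    if strategy is Harmonisation.SPANS_FIRST:
        primary = _spans_only_units(inp)
        claimed = {i for f, l, _ in primary for i in range(f, l + 1)}
        backoff = _truncate_to_unclaimed(_ids_only_units(inp), claimed)
        return _to_annotations(inp, primary + backoff)
    # ids-first
    primary = _ids_only_units(inp)
    claimed = {i for f, l, _ in primary for i in range(f, l + 1)}
    remnants = []
    for first, last, _ in _truncate_to_unclaimed(
        [(f, l, cid) for f, l, cid in _spans_only_units(inp)], claimed
    ):
        # a concept label is always required: remnants must re-pass the
        # dictionary-support test against their truncated extent
        cid = _resolve_from_dict(inp.tokens, first, last, inp.dict_matches)
        if cid is not None:
            remnants.append((first, last, cid))
    return _to_annotations(inp, primary + remnants)
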