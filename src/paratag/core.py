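"""Core domain types and span algebra.

Concept recognition combines named entity recognition (where in the text
a mention sits) with normalisation (which ontology concept it denotes).
The types here model the primitives shared by every other module:
character spans, documents, possibly discontinuous concept annotations,
tokens with their three parallel label channels (IOBES span tag, concept
ID tag, dictionary feature), the ontology used for grounding and
similarity, and the strategy configuration that selects how complex
annotations are flattened and how the channels are merged.

Conventions
-----------
* Character offsets are 0-based and half-open ``[start, end)``, as in
  brat/BioNLP standoff practice.
* ``O`` (span channel) and ``NIL`` (ID channel) are reserved symbols for
  "outside any entity" and may never be used as concept IDs.
* Adjacent fragments of a discontinuous annotation (end of one equals
  start of the next) are merged on construction, as are overlapping
  fragments, so every stored annotation is in a canonical form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import IntegrityError, OffsetError, ParameterError

#: Reserved non-entity symbols; rejected as concept IDs.
NIL = "NIL"
OUTSIDE = "O"
RESERVED_LABELS = frozenset({NIL, OUTSIDE})

#: The five span-channel tags: Begin, Inside, Outside, End, Single.
SPAN_TAGS = frozenset("BIOES")

def is_valid_concept_id(concept_id: str) -> bool:
    """A concept ID is ``PREFIX:LOCAL`` (e.g. ``CHEBI:22720``) and not a
    reserved label."""
    if concept_id in RESERVED_LABELS:
        return False
    return bool(re.fullmatch(r"[^\s:]+:[^\s]+", concept_id))


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)``; never empty."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"invalid span ({self.start}, {self.end}): need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Document:
    """A piece of text with a stable identifier."""

    doc_id: str
    text: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ParameterError("doc_id must be non-empty")


def _normalise_spans(spans: Iterable[Span | tuple[int, int]]) -> tuple[Span, ...]:
    """Sort fragments and merge any that overlap or touch."""
    prepared = [s if isinstance(s, Span) else Span(*s) for s in spans]
    prepared.sort()
    merged: list[Span] = []
    for s in prepared:
        if merged and s.start <= merged[-1].end:
            merged[-1] = Span(merged[-1].start, max(merged[-1].end, s.end))
        else:
            merged.append(s)
    return tuple(merged)


@dataclass(frozen=True)
class Annotation:
    """One concept mention: an ID plus an ordered list of fragments.

    Most mentions are contiguous (one fragment); coordinated phrases like
    "ES ... cells" in "ES and somatic cells" produce discontinuous
    annotations with several non-adjacent fragments.  ``text`` is the
    covered text with fragments joined by a single space.  The annotation
    identifier ``ann_id`` is serialisation plumbing and excluded from
    equality, so round-tripped annotations compare equal even when a
    writer renumbers them.
    """

    ann_id: str = field(compare=False)
    concept_id: str
    spans: tuple[Span, ...]
    text: str = field(default="", compare=False)

    def __init__(
        self,
        ann_id: str,
        concept_id: str,
        spans: Iterable[Span | tuple[int, int]],
        text: str = "",
        document: Document | None = None,
    ):
        if not is_valid_concept_id(concept_id):
            raise IntegrityError(f"invalid concept ID {concept_id!r}")
        norm = _normalise_spans(spans)
        if not norm:
            raise ParameterError(f"annotation {ann_id}: at least one span required")
        object.__setattr__(self, "ann_id", ann_id)
        object.__setattr__(self, "concept_id", concept_id)
        object.__setattr__(self, "spans", norm)
        if document is not None:
            covered = covered_text_of_spans(document, norm, ann_id=ann_id)
            if text and text != covered:
                raise IntegrityError(
                    f"annotation {ann_id}: stated text {text!r} does not match "
                    f"covered text {covered!r} in document {document.doc_id}"
                )
            text = covered
        object.__setattr__(self, "text", text)

    @property
    def start(self) -> int:
        return self.spans[0].start

    @property
    def end(self) -> int:
        return self.spans[-1].end

    @property
    def is_discontinuous(self) -> bool:
        return len(self.spans) > 1


@dataclass(frozen=True)
class Token:
    """A surface string anchored at a character span."""

    surface: str
    span: Span


@dataclass(frozen=True)
class LabelledToken:
    """A token with its three parallel prediction channels."""

    token: Token
    span_tag: str = OUTSIDE
    id_tag: str = NIL
    dict_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.span_tag not in SPAN_TAGS:
            raise IntegrityError(f"unknown span tag {self.span_tag!r}")
        if self.id_tag != NIL and not is_valid_concept_id(self.id_tag):
            raise IntegrityError(f"invalid ID-channel label {self.id_tag!r}")

    def replace(self, **kwargs) -> "LabelledToken":
        base = dict(
            token=self.token,
            span_tag=self.span_tag,
            id_tag=self.id_tag,
            dict_ids=self.dict_ids,
        )
        base.update(kwargs)
        return LabelledToken(**base)


@dataclass(frozen=True)
class Concept:
    id: str
    name: str
    synonyms: frozenset[str]
    parents: frozenset[str]


class Ontology:
    """Concept graph with ``is_a`` parents and ancestor queries.

    Validated on construction: every parent reference must resolve and
    the ``is_a`` graph must be acyclic, so ancestor queries always
    terminate.
    """

    def __init__(self, concepts: Mapping[str, Concept]):
        self._concepts = dict(concepts)
        graph = {}
        for cid, concept in self._concepts.items():
            for parent in concept.parents:
                if parent not in self._concepts:
                    raise IntegrityError(
                        f"concept {cid} has unresolved parent {parent}"
                    )
            graph[cid] = set(concept.parents)
        try:
            list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise IntegrityError(f"is_a cycle detected: {exc.args[1]}") from exc
        self._ancestors: dict[str, frozenset[str]] = {}

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self._concepts[concept_id]

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[str]:
        return iter(self._concepts)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self._concepts)

    def ancestors(self, concept_id: str) -> frozenset[str]:
        """Self-inclusive transitive ``is_a`` closure of ``concept_id``."""
        cached = self._ancestors.get(concept_id)
        if cached is not None:
            return cached
        concept = self._concepts[concept_id]
        result = {concept_id}
        for parent in concept.parents:
            result |= self.ancestors(parent)
        frozen = frozenset(result)
        self._ancestors[concept_id] = frozen
        return frozen


class Unification(str, Enum):
    """How a discontinuous annotation collapses to one contiguous span."""

    FIRST_SPAN = "first-span"
    FULL_SPAN = "full-span"
    LAST_SPAN = "last-span"


class Unnesting(str, Enum):
    """Which of two overlapping annotations survives flattening."""

    KEEP_LONGER = "keep-longer"
    KEEP_SHORTER = "keep-shorter"


class Harmonisation(str, Enum):
    """How the span, ID and dictionary channels merge into one output."""

    SPANS_ONLY = "spans-only"
    IDS_ONLY = "ids-only"
    SPANS_FIRST = "spans-first"
    IDS_FIRST = "ids-first"


@dataclass(frozen=True)
class StrategyConfig:
    """The system's central hyperparameters.

    Defaults are first-span/keep-longer (the flattening pair with the
    highest round-trip upper bound) and spans-first harmonisation; the
    right harmonisation strategy is corpus-dependent and should be
    calibrated on a development set.
    """

    unification: Unification = Unification.FIRST_SPAN
    unnesting: Unnesting = Unnesting.KEEP_LONGER
    harmonisation: Harmonisation = Harmonisation.SPANS_FIRST

    def __post_init__(self) -> None:
        object.__setattr__(self, "unification", Unification(self.unification))
        object.__setattr__(self, "unnesting", Unnesting(self.unnesting))
        object.__setattr__(self, "harmonisation", Harmonisation(self.harmonisation))


# ---------------------------------------------------------------------------
# span algebra


def covered_text_of_spans(
    document: Document, spans: Sequence[Span], ann_id: str = "?"
) -> str:
    """Fragment substrings of ``document`` joined by a single space."""
    n = len(document.text)
    for span in spans:
        if span.end > n:
            raise OffsetError(
                f"annotation {ann_id}: span ({span.start}, {span.end}) outside "
                f"document {document.doc_id!r} of length {n}"
            )
    return " ".join(document.text[s.start : s.end] for s in spans)


def covered_text(document: Document, annotation: Annotation) -> str:
    """The text an annotation covers, fragments joined by one space."""
    return covered_text_of_spans(document, annotation.spans, annotation.ann_id)


def spans_overlap(a: Sequence[Span], b: Sequence[Span]) -> bool:
    """True iff any character offset is covered by both span lists."""
    return any(sa.overlaps(sb) for sa in a for sb in b)


def total_length(annotation: Annotation) -> int:
    """Number of characters the annotation covers across all fragments."""
    return sum(len(s) for s in annotation.spans)
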