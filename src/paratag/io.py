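"""Readers and writers: brat-style standoff, the CoNLL dialect, OBO-lite.

Standoff dialect
    One annotation per line, four tab-separated fields::

        T1 <TAB> GO:0005622 <TAB> 0 4 <TAB> cell
        T2 <TAB> CL:0000000 <TAB> 0 2;15 20 <TAB> ES cells

    Discontinuous fragments are ";"-separated ``start end`` pairs and
    their texts are joined by a single space.  Lines starting with ``#``
    are comments.

CoNLL dialect
    Six tab-separated columns: TOKEN, START, END, DICT, SPAN, ID.  DICT
    is ``-`` or a ``|``-joined, lexically sorted list of concept IDs;
    SPAN is an IOBES tag; ID is a concept ID or ``NIL``.  ``# doc_id =
    X`` starts a new document; blank lines (sentence breaks) are
    tolerated on input and never emitted.

All files are UTF-8 with ``\\n`` line endings; writers are exact
inverses of the readers on valid in-memory data.

OBO parsing is delegated to :mod:`obonet`; only ``is_a`` relations are
kept, obsolete stanzas are skipped, and the primary name is included
among the synonyms.
"""

from __future__ import annotations

import io
import re
from typing import Iterable, Sequence, TextIO

import obonet

from .core import (
    NIL,
    SPAN_TAGS,
    Annotation,
    Concept,
    Document,
    LabelledToken,
    Ontology,
    Span,
    Token,
    is_valid_concept_id,
)
from .errors import IntegrityError, ParseError

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _as_stream(source: TextIO | str) -> TextIO:
    return io.StringIO(source) if isinstance(source, str) else source


# ---------------------------------------------------------------------------
# standoff


def read_standoff(
    source: TextIO | str,
    document: Document | None = None,
    verify_text: bool = True,
) -> list[Annotation]:
    """Parse brat-style standoff lines into annotations.

    When ``document`` is given (and ``verify_text`` is true) each
    annotation's stated text is checked against the covered document
    text; a mismatch raises :class:`IntegrityError` naming the
    annotation.
    """
    annotations = []
    for lineno, raw in enumerate(_as_stream(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 tab-separated fields, got {len(fields)}", lineno
            )
        ann_id, concept_id, offsets, text = fields
        spans = []
        for frag in offsets.split(";"):
            parts = frag.split()
            if len(parts) != 2:
                raise ParseError(f"malformed offset pair {frag!r}", lineno)
            try:
                start, end = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer offset in {frag!r}", lineno) from None
            spans.append((start, end))
        annotations.append(
            Annotation(
                ann_id,
                concept_id,
                spans,
                text,
                document=document if verify_text else None,
            )
        )
    return annotations


def write_standoff(annotations: Iterable[Annotation]) -> str:
    """Serialise annotations, sorted by start, end, then concept ID.

    Annotation identifiers are renumbered ``T1``... in output order.
    """
    ordered = sorted(
        annotations, key=lambda a: (a.start, a.end, a.concept_id)
    )
    lines = []
    for n, ann in enumerate(ordered, start=1):
        offsets = ";".join(f"{s.start} {s.end}" for s in ann.spans)
        lines.append(f"T{n}\t{ann.concept_id}\t{offsets}\t{ann.text}\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# CoNLL dialect

_CONLL_HEADER_RE = re.compile(r"^# doc_id = (.+)$")


def read_conll(source: TextIO | str) -> list[tuple[Document, list[LabelledToken]]]:
    """Parse the CoNLL dialect into per-document labelled token lists.

    The returned documents are stubs (identifier only, empty text): the
    running text is not recoverable from token rows alone.
    """
    results: list[tuple[Document, list[LabelledToken]]] = []
    tokens: list[LabelledToken] | None = None
    for lineno, raw in enumerate(_as_stream(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue  # sentence break
        header = _CONLL_HEADER_RE.match(line)
        if header:
            tokens = []
            results.append((Document(header.group(1)), tokens))
            continue
        if line.startswith("#"):
            continue
        if tokens is None:
            raise ParseError("token row before any '# doc_id = ...' header", lineno)
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(
                f"expected 6 tab-separated fields, got {len(fields)}", lineno
            )
        surface, start_s, end_s, dict_field, span_tag, id_tag = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError("non-integer token offsets", lineno) from None
        if span_tag not in SPAN_TAGS:
            raise ParseError(f"unknown span tag {span_tag!r}", lineno)
        if id_tag != NIL and not is_valid_concept_id(id_tag):
            raise ParseError(f"invalid ID label {id_tag!r}", lineno)
        if dict_field == "-":
            dict_ids: frozenset[str] = frozenset()
        else:
            parts = dict_field.split("|")
            if parts != sorted(set(parts)):
                raise ParseError(
                    f"dictionary field {dict_field!r} not sorted/unique", lineno
                )
            if not all(is_valid_concept_id(p) for p in parts):
                raise ParseError(f"invalid dictionary ID in {dict_field!r}", lineno)
            dict_ids = frozenset(parts)
        tokens.append(
            LabelledToken(
                token=Token(surface, Span(start, end)),
                span_tag=span_tag,
                id_tag=id_tag,
                dict_ids=dict_ids,
            )
        )
    return results


def write_conll(
    documents: Sequence[tuple[Document, Sequence[LabelledToken]]]
) -> str:
    """Serialise documents with labelled tokens; inverse of read_conll."""
    out: list[str] = []
    for doc, tokens in documents:
        out.append(f"# doc_id = {doc.doc_id}\n")
        for lt in tokens:
            dict_field = "|".join(sorted(lt.dict_ids)) if lt.dict_ids else "-"
            out.append(
                f"{lt.token.surface}\t{lt.token.span.start}\t{lt.token.span.end}"
                f"\t{dict_field}\t{lt.span_tag}\t{lt.id_tag}\n"
            )
    return "".join(out)


# ---------------------------------------------------------------------------
# OBO-lite


def read_obo_lite(source: TextIO | str) -> Ontology:
    """Parse an OBO 1.2 subset (id, name, synonym, is_a) into an Ontology.

    Obsolete stanzas are skipped; ``is_a`` references to missing
    concepts and cycles raise :class:`IntegrityError`.
    """
    try:
        graph = obonet.read_obo(_as_stream(source), ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subtypes
        raise ParseError(f"malformed OBO input: {exc}") from exc
    concepts: dict[str, Concept] = {}
    for cid, data in graph.nodes(data=True):
        if "name" not in data:
            # node materialised only as an is_a target of another stanza
            raise IntegrityError(f"is_a reference to undefined concept {cid}")
    for cid, data in graph.nodes(data=True):
        name = data["name"]
        synonyms = {name}
        for raw in data.get("synonym", ()):
            m = _SYNONYM_RE.match(raw)
            if m:
                synonyms.add(m.group(1).replace('\\"', '"'))
        parents = frozenset(
            v for _, v, key in graph.out_edges(cid, keys=True) if key == "is_a"
        )
        concepts[cid] = Concept(cid, name, frozenset(synonyms), parents)
    return Ontology(concepts)  # raises IntegrityError on is_a cycles


def write_obo_lite(ontology: Ontology) -> str:
    """Serialise an Ontology in the OBO subset read_obo_lite accepts."""
    out = ["format-version: 1.2\n"]
    for cid in sorted(ontology.ids):
        concept = ontology[cid]
        out.append(f"\n[Term]\nid: {cid}\nname: {concept.name}\n")
        for syn in sorted(concept.synonyms - {concept.name}):
            escaped = syn.replace('"', '\\"')
            out.append(f'synonym: "{escaped}" EXACT []\n')
        for parent in sorted(concept.parents):
            out.append(f"is_a: {parent} ! {ontology[parent].name}\n")
    return "".join(out)
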