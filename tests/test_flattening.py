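"""Tokenisation, flattening pipeline and IOBES encode/decode."""

import itertools

import pytest

from paratag import (
    Annotation,
    Document,
    LabelledToken,
    Span,
    StrategyConfig,
    Token,
    Unification,
    Unnesting,
    decode_entities,
    encode_labels,
    snap_to_token_boundaries,
    tokenize,
    unify_discontinuous,
    unnest_overlaps,
)
from paratag.errors import ConsistencyError, DegenerateSpanError
from paratag.fixtures import CorpusSpec, fig2_fixture, gen_corpus, gen_ontology
from paratag.flattening import FlatAnnotation, flatten_annotations

ALL_CONFIGS = [
    StrategyConfig(unification=u, unnesting=n)
    for u, n in itertools.product(Unification, Unnesting)
]


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Ephrin-B1", ["Ephrin", "-", "B1"]),
            ("ES and somatic cells", ["ES", "and", "somatic", "cells"]),
            ("", []),
        ],
    )
    def test_surfaces(self, text, expected):
        assert [t.surface for t in tokenize(Document("d", text))] == expected

    def test_offsets(self):
        tokens = tokenize(Document("d", "ES and somatic cells"))
        assert [(t.span.start, t.span.end) for t in tokens] == [
            (0, 2), (3, 6), (7, 14), (15, 20),
        ]

    def test_every_non_space_character_covered(self):
        text = "p53-dependent (x2): done."
        tokens = tokenize(Document("d", text))
        covered = {o for t in tokens for o in range(t.span.start, t.span.end)}
        assert covered == {i for i, c in enumerate(text) if not c.isspace()}


class TestUnify:
    DISC = Annotation("T1", "X:1", [(0, 2), (15, 20)])

    @pytest.mark.parametrize(
        "strategy,expected",
        [("first-span", (0, 2)), ("full-span", (0, 20)), ("last-span", (15, 20))],
    )
    def test_strategies(self, strategy, expected):
        flat = unify_discontinuous(self.DISC, strategy)
        assert (flat.start, flat.end) == expected

    @pytest.mark.parametrize("strategy", list(Unification))
    def test_contiguous_passes_through(self, strategy):
        ann = Annotation("T1", "X:1", [(7, 20)])
        assert unify_discontinuous(ann, strategy).span == Span(7, 20)


class TestUnnest:
    A = FlatAnnotation("X:A", Span(0, 20))
    B = FlatAnnotation("X:B", Span(7, 20))

    def test_keep_longer(self):
        assert unnest_overlaps([self.A, self.B], "keep-longer") == [self.A]

    def test_keep_shorter(self):
        assert unnest_overlaps([self.A, self.B], "keep-shorter") == [self.B]

    @pytest.mark.parametrize("strategy", list(Unnesting))
    def test_disjoint_both_kept(self, strategy):
        disjoint = [FlatAnnotation("X:A", Span(0, 2)), self.B]
        assert unnest_overlaps(disjoint, strategy) == disjoint

    def test_length_tie_broken_by_start_then_concept(self):
        a = FlatAnnotation("X:B", Span(0, 5))
        b = FlatAnnotation("X:A", Span(0, 5))
        c = FlatAnnotation("X:C", Span(3, 8))
        assert unnest_overlaps([a, b, c], "keep-longer") == [b]


class TestSnap:
    TOKENS = tokenize(Document("d", "hexokinase binds"))

    def test_subword_extends_to_token(self):
        flat = FlatAnnotation("X:1", Span(0, 4))
        assert snap_to_token_boundaries(flat, self.TOKENS).span == Span(0, 10)

    def test_aligned_is_idempotent(self):
        flat = FlatAnnotation("X:1", Span(0, 10))
        snapped = snap_to_token_boundaries(flat, self.TOKENS)
        assert snapped.span == Span(0, 10)
        assert snap_to_token_boundaries(snapped, self.TOKENS) == snapped

    def test_union_of_two_tokens(self):
        tokens = tokenize(Document("d", "ab cde"))
        flat = FlatAnnotation("X:1", Span(0, 6))
        assert snap_to_token_boundaries(flat, tokens).span == Span(0, 6)

    def test_whitespace_only_span_raises(self):
        with pytest.raises(DegenerateSpanError):
            snap_to_token_boundaries(
                FlatAnnotation("X:1", Span(10, 11)), self.TOKENS
            )


class TestEncode:
    def test_single_token_entity_is_S(self):
        doc = Document("d", "mouse runs")
        labelled = encode_labels(
            doc, [Annotation("T1", "X:1", [(0, 5)])], StrategyConfig()
        )
        assert [lt.span_tag for lt in labelled] == ["S", "O"]
        assert [lt.id_tag for lt in labelled] == ["X:1", "NIL"]

    def test_three_token_entity_is_BIE(self):
        doc = Document("d", "red blood cell count")
        labelled = encode_labels(
            doc, [Annotation("T1", "X:1", [(0, 14)])], StrategyConfig()
        )
        assert [lt.span_tag for lt in labelled] == ["B", "I", "E", "O"]

    def test_no_annotations_all_outside(self):
        doc = Document("d", "nothing here")
        labelled = encode_labels(doc, [], StrategyConfig())
        assert all(lt.span_tag == "O" and lt.id_tag == "NIL" for lt in labelled)


def _lt(surface, start, tag, cid):
    return LabelledToken(
        token=Token(surface, Span(start, start + len(surface))),
        span_tag=tag,
        id_tag=cid,
    )


class TestDecode:
    def test_single_S(self):
        anns = decode_entities([_lt("a", 0, "S", "X:1")])
        assert anns == [Annotation("T1", "X:1", [(0, 1)])]

    def test_BE_pair(self):
        anns = decode_entities([_lt("ab", 0, "B", "X:1"), _lt("cd", 3, "E", "X:1")])
        assert anns == [Annotation("T1", "X:1", [(0, 5)])]

    @pytest.mark.parametrize(
        "tokens",
        [
            [_lt("a", 0, "E", "X:1")],  # E with no open entity
            [_lt("a", 0, "B", "X:1")],  # unclosed B
            [_lt("a", 0, "B", "X:1"), _lt("b", 2, "E", "X:2")],  # ID change
            [_lt("a", 0, "O", "X:1")],  # O with non-NIL ID
            [_lt("a", 0, "S", "NIL")],  # entity tag without ID
        ],
    )
    def test_strict_rejects_ill_formed(self, tokens):
        with pytest.raises(ConsistencyError):
            decode_entities(tokens, repair=False)

    def test_repair_splits_at_id_change(self):
        tokens = [_lt("a", 0, "B", "X:1"), _lt("b", 2, "E", "X:2")]
        anns = decode_entities(tokens, repair=True)
        assert [(a.concept_id, a.start, a.end) for a in anns] == [
            ("X:1", 0, 1), ("X:2", 2, 3),
        ]

    def test_repair_orphan_inside_acts_as_begin(self):
        tokens = [_lt("a", 0, "I", "X:1"), _lt("b", 2, "I", "X:1")]
        anns = decode_entities(tokens, repair=True)
        assert [(a.concept_id, a.start, a.end) for a in anns] == [("X:1", 0, 3)]

    def test_repair_interrupted_entity_closes_early(self):
        tokens = [_lt("a", 0, "B", "X:1"), _lt("b", 2, "O", "NIL"),
                  _lt("c", 4, "S", "X:2")]
        anns = decode_entities(tokens, repair=True)
        assert [(a.concept_id, a.start, a.end) for a in anns] == [
            ("X:1", 0, 1), ("X:2", 4, 5),
        ]


class TestPipeline:
    def test_fig2_produces_four_distinct_outcomes(self):
        doc, gold = fig2_fixture()
        outcomes = {
            frozenset(
                (f.concept_id, f.start, f.end)
                for f in flatten_annotations(doc, gold, cfg)
            )
            for cfg in ALL_CONFIGS
        }
        assert len(outcomes) == 4
        assert sum(1 for o in outcomes if len(o) == 1) == 3

    def test_first_span_outcome_keeps_both_annotations(self):
        doc, gold = fig2_fixture()
        cfg = StrategyConfig(unification="first-span", unnesting="keep-longer")
        flats = flatten_annotations(doc, gold, cfg)
        assert [(f.start, f.end) for f in flats] == [(0, 2), (7, 20)]

    @pytest.mark.parametrize("cfg", ALL_CONFIGS, ids=str)
    def test_flattening_never_increases_count(self, cfg):
        ontology = gen_ontology(12, seed=3)
        corpus = gen_corpus(
            ontology,
            CorpusSpec(n_docs=2, sentences_per_doc=6, p_discontinuous=0.3,
                       p_overlap=0.3, seed=3),
        )
        for doc, gold in corpus.train + corpus.test:
            assert len(flatten_annotations(doc, gold, cfg)) <= len(gold)

    @pytest.mark.parametrize("cfg", ALL_CONFIGS, ids=str)
    def test_encoded_labels_always_strictly_decodable(self, cfg):
        ontology = gen_ontology(12, seed=9)
        corpus = gen_corpus(
            ontology,
            CorpusSpec(n_docs=2, sentences_per_doc=6, p_discontinuous=0.3,
                       p_overlap=0.3, p_ambiguous_surface=0.2, seed=9),
        )
        for doc, gold in corpus.train + corpus.test:
            labelled = encode_labels(doc, gold, cfg)
            decoded = decode_entities(labelled, repair=False, document=doc)
            flats = flatten_annotations(doc, gold, cfg)
            assert [(a.concept_id, a.start, a.end) for a in decoded] == [
                (f.concept_id, f.start, f.end) for f in flats
            ]
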