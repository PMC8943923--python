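# Methods

## Problem setting

Concept recognition in biomedical text combines two subtasks: finding
mention spans (named entity recognition) and grounding each mention in
an ontology concept (normalisation).  Pipelines that normalise the
output of a span tagger propagate span errors into grounding.  The
alternative implemented here runs the two as *parallel* sequence
taggers over the same token sequence — an IOBES span channel and a
concept-ID channel — alongside a knowledge-based dictionary channel,
and merges the three afterwards.  The framework covers the full loop:
lossy flattening of rich standoff annotations into token labels,
prediction channels, harmonisation of the channels into final
annotations, and similarity-weighted evaluation including an
unseen-concept protocol.

## Flattening: standoff to token labels

Token-per-row representations force exactly one label per token, so
three annotation phenomena must be simplified:

* **Discontinuous mentions** (coordinations like "ES … cells") are
  *unified* to one contiguous span: `first-span` keeps the first
  fragment, `last-span` the last, `full-span` the envelope from first
  start to last end.
* **Sub-word spans** are *snapped* outward to whole-token boundaries
  (idempotent; a span covering no token is an error).
* **Overlapping annotations** are *unnested* greedily: candidates are
  ranked by length (descending for `keep-longer`, ascending for
  `keep-shorter`), then start offset, then concept ID, and accepted
  while they overlap nothing already accepted.  The published
  behaviour defines only the pairwise preference; the rank order with
  its two tie-breaks is this package's deterministic generalisation to
  larger overlap clusters.

The pipeline order is unify → snap → unnest: snapping can create new
overlaps, so unnesting must run last.  Flattening never increases the
annotation count, and on corpora whose gold is contiguous,
token-aligned and non-overlapping it is exactly invertible — encode
followed by decode reproduces the gold for every strategy pair, which
the round-trip tests check end to end through the serialisers.

Tokenisation is deliberately simple and language-independent: maximal
runs of Unicode letters and digits, with every other non-space
character (including `_`) a single-character token.  "Ephrin-B1" is
three tokens, so sub-word annotations such as "Ephrin" alone snap to a
clean token boundary rather than splitting a token.

Decoding accepts well-formed IOBES/ID sequences strictly, or repairs
predicted sequences with four deterministic rules: an orphan `I`/`E`
opens an entity (R1); an interrupted entity closes at the previous
token (R2); an ID change inside an entity splits it (R3, only when the
ID channel participates); a concept ID under an `O` tag opens a
single-token entity only when the caller enables ID-driven decoding
(R4, used by harmonisation backoff, not by plain decoding).

## Prediction channels

The **dictionary tagger** indexes every ontology name and synonym
(plus caller-supplied extra synonyms) under a normalised form —
lower-cased, punctuation to spaces, whitespace collapsed — and reports
every token n-gram whose normalised text is indexed, nested and
overlapping matches included.  Matching is exact over normalised
n-grams; fuzzier matching is intentionally out of scope so that every
match is auditable, with the normalisation function carrying the
robustness (case, hyphenation, spacing).

The **memorisation tagger** is the minimal example-based classifier:
it memorises the normalised surfaces of flattened training annotations
with concept-ID frequency tables, and at prediction time re-tags known
surfaces greedily (longest match, left to right), emitting the
surface's most frequent ID with frequency ties broken toward the
lexically lowest ID.  It exists to reproduce, by construction, the
defining structural property of trained sequence taggers — the label
set is limited to IDs seen in training — which drives the
unseen-concept analysis.  It does not model contextual generalisation;
real classifier output can be imported through the CoNLL reader and
harmonised identically.

The **corruption oracle** perturbs gold label sequences per entity and
per channel, independently: with `p_drop` the entity vanishes from a
channel, with `p_span_flip` one boundary of the span-channel entity
moves by one token where space permits, with `p_id_swap` the ID
channel's concept is replaced by a uniformly drawn different label.
All draws come from one seeded generator, so disagreement patterns are
exactly reproducible.

## Harmonisation

Each token's three channels are each either relevant or not, giving
2×2×2 = 8 disagreement patterns.  Four fixed-bias strategies resolve
them:

* **spans-only** — boundaries from the IOBES channel (repair rules,
  ID channel ignored); each entity takes the concept of the
  overlapping dictionary match with the highest character Jaccard
  against it, ties to the lexically lowest ID.  A concept label being
  mandatory, span entities with no dictionary support are dropped.
* **ids-only** — maximal runs of one non-NIL concept in the ID channel
  become annotations; span tags and dictionary are overridden.
* **spans-first / ids-first** — the preferred strategy runs first and
  claims its tokens; entities of the other strategy are truncated to
  their maximal contiguous runs of unclaimed tokens and appended.
  Backoff is therefore token-granular while ID assignment stays
  entity-level.  Under ids-first, truncated span remnants must re-pass
  the dictionary-support test against their reduced extent (a concept
  label is always required); empty remnants disappear.

Structural guarantees, all property-tested: outputs are pairwise
non-overlapping; spans-only ⊆ spans-first and ids-only ⊆ ids-first as
(span, ID) sets; with channels derived consistently from the same gold,
all four strategies return the flattened gold; ids-only can never emit
a concept absent from the ID channel, which is why it predicts nothing
in the unseen-concept evaluation, and why spans-only and spans-first
coincide there (their difference is exactly the filtered-out backoff).

## Evaluation

A reference–prediction pair with textual overlap is scored by the
fractional similarity `m = j · c`: `j` is the character-level Jaccard
index of the span sets, and `c` is 1 for identical concepts, else the
Jaccard index of the two self-inclusive `is_a` ancestor sets.  The
product form makes `m = 1` exactly on perfect predictions and `m = 0`
when either component vanishes; depth-weighting of ancestors is a
documented extension point, deliberately omitted.  Pairing requires
`j > 0` but not `c > 0`, so a wrong-concept overlap counts as a
substitution rather than an insertion+deletion.

Alignment is greedy over candidate pairs sorted by (`m` desc, `j`
desc, reference start, prediction start): deterministic and O(n² log n).
An exhaustive optimal-assignment oracle bounds the gap in the tests;
greedy carries the classic factor-2 matching guarantee, and on all
sampled instances it attained the optimum (the acceptance script
reports the measured maximum gap).

Accepted pairs add `m` to matches and `1−m` to substitutions;
unmatched references are deletions, unmatched predictions insertions.
Then `P = M/(M+S+I)`, `R = M/(M+S+D)`, `F = 2PR/(P+R)` (0 when both
vanish) and `SER = (S+I+D)/(M+S+D)`.  SER is 0 for a perfect system,
may exceed 1, and punishes insertions relative to the reference size —
hence `SER = 1 − R` exactly when there are no insertions, an identity
the tests assert.  Conventions for empty sides: both empty is
vacuously perfect (`P = R = F = 1`, `SER = 0`); an empty reference
with predictions leaves SER undefined and it is reported as `None`,
never as a number.

The unseen-concept protocol filters **both** reference and predictions
down to concept IDs absent from the training annotations before
counting, isolating the ability to predict novel concepts.

## Synthetic data

The generators are pure functions of (parameters, seed); every
experiment in the tests and the acceptance script runs on them, with
no external download.

`gen_ontology` builds a rooted acyclic `is_a` graph (`SYN:0000001`…,
each non-root with 1..`max_parents` parents among earlier concepts)
with unique pronounceable names, one two-word synonym per concept and
further single-word synonyms; a `p_ambiguous` option reuses an earlier
synonym to create genuinely ambiguous surface forms.

`gen_corpus` assembles documents from filler-word sentences (filler
vocabulary disjoint from all ontology terms) and plants, per sentence
with probability `mention_rate`, one of: a plain mention (a synonym of
the concept); a discontinuous coordination "a₁ and b₁ h" annotating
a₁+h discontinuously and b₁ h contiguously (the two-annotation overlap
pattern of coordinated noun phrases); a nested pair "w₁ w₂" / "w₂"; or
an ambiguous surface shared by two concepts.  Invented surfaces are
returned as extra synonyms, so the generated lexicon covers every
contiguous planted mention — dictionary recall on uncorrupted fixtures
is 1 by construction, a deliberate property so that failures isolate
the component under test rather than lexicon gaps.

The train/test split reserves exactly ⌈`unseen_fraction` ·
n_concepts⌉ concepts for the test gold.  Coverage documents force
every remaining concept into train and every reserved concept into
test, so the test-only concept set equals the reserved set exactly.
The split sizes — `n_docs` training documents plus ⌈`n_docs`/2⌉ test
documents — are this package's convention.

Defaults (4 documents of 8 sentences, mention rate 0.8, structural
probabilities 0–0.2 in the tests, unseen fraction 0.3 for the
unseen-protocol experiments) keep corpora at desk scale: a few hundred
tokens and a few dozen annotations per corpus, which exercises every
code path while the whole suite runs in seconds.

What the generator does *not* emulate: biomedical vocabulary and
syntax, Zipfian concept frequencies, sub-word annotations inside
tokens, contextual disambiguation, and annotation-set idiosyncrasies
of real corpora.  Passing tests therefore demonstrate the mechanics
and invariants of flattening/harmonisation/evaluation, not expected
performance on real text.

## Numerical and degenerate-input choices

* Character offsets are 0-based half-open; empty spans are invalid;
  adjacent or overlapping fragments of one annotation merge on
  construction, making annotation normalisation idempotent.
* `O`/`NIL` are reserved and rejected as concept IDs; concept IDs must
  look like `PREFIX:LOCAL`.
* Count conservation (`M+S+D = |ref|`, `M+S+I = |pred|`) is checked to
  1e-9; fractional arithmetic is plain floating point.
* All tie-breaks (unnesting, dictionary candidate ranking, frequency
  ties, alignment ordering) resolve by explicit lexicographic keys so
  every operation is deterministic and order-independent.
* Sides with internally overlapping annotations are rejected by the
  aligner: flattening must be applied first.

## Known limitations

* No claim of byte-for-byte parity with the official CRAFT evaluation
  suite: the exact similarity formula of that suite is not public in
  the source used here, and `m = j·c` is a documented stand-in.  The
  `roundtrip` CLI command reproduces the flattening upper-bound
  experiment for users who have CRAFT and the official scorer.
* The dictionary tagger's exact n-gram matching under-approximates
  fuzzy matchers on real text (morphological variants, misspellings).
* Neural taggers are integration points (CoNLL import), not
  components; the memorisation tagger is a structural stand-in only.
* Greedy alignment is specified behaviour; pathological instances can
  in principle fall below the optimum (never below half of it), which
  the oracle-backed tests and the acceptance report quantify.
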