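# Methods

## Document model

A document is `(doc_id, text, properties, entities, relations)`. Text is
NFC-normalized Unicode; all offsets are 0-based half-open `[start, end)`
counted in code points, and every stored span must re-slice to its recorded
surface string (`text[start:end] == surface`) — validation is total and
reports every violation, not just the first. Entity types come from a fixed
vocabulary (`gene`, `protein`, `mirna`, `disease`, `chemical`, `mutation`,
`trigger`, `outcome`, `other`). Relations reference entities by key through
named roles and may carry an evidence span.

Serialization is canonical JSON: keys sorted, except `properties`, which is
an insertion-ordered map and serialized in that order; `ensure_ascii=False`;
compact separators. Equal documents therefore serialize to identical bytes,
which is what makes "lossless round-trip" a byte-level statement and
determinism tests meaningful. Collections are newline-delimited JSON.

## Alignment

**Scoring.** Unit scoring: match +1, mismatch −1, gap −1 (configurable; the
constructor rejects non-negative mismatch/gap and non-positive match).
Because mismatch > 2·gap is *not* satisfied in reverse — i.e. a
substitution (−1) is strictly cheaper than an insert+delete pair (−2) —
optimal alignments never contain an adjacent INSERT/DELETE pair, a fact the
canonicalization step (below) relies on.

**Full-matrix oracle.** `align_full` computes the suffix-score matrix
`B[i][j]` = optimal score of aligning `a[i:]` with `b[j:]`, then walks from
`(0,0)` preferring diagonal (MATCH/SUBST), then DELETE, then INSERT at every
tie. This yields one deterministic, documented, front-to-back tie-break and
is the reference implementation for tests. Rows are filled with vectorized
numpy max-plus prefix scans (`np.maximum.accumulate`) so the in-row gap
chain needs no Python loop.

**Linear-space alignment.** `align_hirschberg` is Hirschberg's
divide-and-conquer: a two-row forward Needleman–Wunsch pass over the first
half and a backward pass over the reversed second half locate the optimal
crossing column (smallest argmax, for determinism); recursion on the two
sub-problems reconstructs the operations in O(nm) time and O(min(n,m))
space. At the top level the shorter string is placed on the row axis (ops
are transposed back afterwards), bounding every scoring buffer by
2·(min(n,m)+1) cells; an optional `stats` dict records the observed
`max_buffer_cells` so the space contract is testable rather than asserted.

**Canonicalization.** Hirschberg recombination can place a diagonal op at
either end of an adjacent gap run (co-optimal paths). `_canonicalize_ops`
bubbles each diagonal op to the earliest position within a trailing pure
INSERT (or DELETE) run at which its match/substitution character status is
preserved. This is score-preserving by construction (verified by replay) and
makes the op sequence — hence the offset map — independent of the recursion's
split choices in the cases that matter for span recovery (e.g. a Greek
letter substituted at the *start* of its transliteration, not the end).
Operation sequences are guaranteed identical to the oracle's only up to
score equality plus this canonicalization; remaining co-optimal
MATCH-placement ties in mixed runs are left as the recursion produces them.

**Offset maps and remapping.** The op sequence induces `to_original`:
modified positions consumed by MATCH/SUBST map to the original index,
INSERT positions are `UNALIGNED` (`None`). `remap_span(start, end, map)`
returns the span from the smallest to the largest aligned original position
inside the query — spans *shrink* across insertions, so a mapped span is
always a substring of the original text — or `UNMAPPED` if no position is
aligned. `realign_document` remaps every entity and relation-evidence span,
drops entities that map to nothing and relations that lose an argument
(logging each), nulls unmappable evidence spans, and can append per-item
audit records. Identical texts short-circuit to the identity map.

## Normalization, merging, network

**Entity normalization** attaches a named-entity recognizer's identifiers
(PubTator-style TSV: `doc  start  end  surface  type  source:id`) to tool
entities by maximum character overlap, earliest start on ties, requiring
type compatibility (gene/protein/mirna are mutually compatible; other types
match only themselves). Candidate order is made irrelevant by ranking on the
full tuple `(-overlap, start, end, source, identifier)`.

**Merging** combines per-tool documents with identical `doc_id` and text
(differing text is an error directing the caller to realign first). Keys are
namespaced `tool.key` unless already prefixed; entities identical in
`(span, type, norm_ids)` and relations identical in `(type, arguments,
evidence)` collapse to one item whose `tool` field is the comma-join of the
contributing tools. Merging is idempotent: merging a merged document with
itself changes nothing.

**Network.** Node identity prefers UniProt, then NCBI gene IDs, then any
normalized ID, then the whitespace-normalized surface form
(`mention:<surface>`). Each relation contributes one evidence item
`(doc_id, tool, relation_key)`; for n-ary relations the edge connects the
first two distinct nodes in role-name-sorted order (a self-loop if all
arguments merge), so total edge weight equals the number of distinct
evidence items exactly — the conservation invariant the tests check. Build
order over documents/entities/relations is sorted, making the network
independent of input order. Export: plain JSON (sorted) and GraphML via a
`networkx` MultiGraph keyed by relation type.

**Coverage statistics** tabulate documents by the number of distinct
contributing tools. Percentages are computed with `decimal` and
ROUND_HALF_UP at two places — binary floats round 0.145 the wrong way —
which is what lets published percentage tables be reproduced digit-for-digit
from their count columns.

## Corpus I/O

Medline citation XML → one document per citation (title + blank line +
abstract; journal/year/abstract-presence as properties; missing PMID is an
error naming the citation's index). PMC JATS → one document per paragraph
(`PMCID.index`), with section types taken from `sec-type` attributes or
title keywords, and figure/table captions typed separately; an empty body is
a warning, not an error. Trigger filtering is a case-insensitive regex
search over document text. BioC XML is emitted and parsed with `lxml`
(offset+length locations, infons for types/tools/norm-ids; a parsed
annotation whose location does not re-slice to its surface raises
`BiocValidationError`). brat standoff emits `T`/`R` lines with role-sorted
arguments.

## Synthetic corpus and perturbations

The generator plants sentences from four relation templates
(phosphorylation, protein–protein interaction, miRNA–target, drug–response)
over a fixed vocabulary of real-looking entities with genuine-format
identifiers (UniProt, NCBI gene, DOID, MeSH), several deliberately
containing Greek letters (NF-κB, IκBα, CK2α, TGF-β1…) and typographic
quotes. Every planted span is recorded as ground truth and re-slices to its
surface.

Five perturbation kinds model real tool preprocessing: space insertion
before punctuation, Greek-letter transliteration (α→alpha etc.), markup-tag
insertion, whitespace collapsing, and curly→ASCII quote substitution. Each
is implemented as a character emitter producing `(char, original_index|None)`
pairs, so the ground-truth offset map is exact *by construction*, not
derived from any aligner; sequential perturbations compose their maps. Mock
tool outputs apply the perturbations, carry the planted annotations at
perturbed offsets, strip normalized IDs (tools report surface mentions), and
are split per owning tool.

Generator defaults — 500 documents, 2–4 sentences each, each perturbation
kind at rate 0.3 — are the study conditions; they were fixed before
measurement and are not tuned to outcomes. Scope limits: sentences are
templated (no syntactic variety, negation, or coordination), perturbations
are independent per site, and entity vocabulary is small, so recovery rates
here bound only the offset machinery, not NER/RE quality.

## Pipeline and CLI

`chunk_corpus` splits a corpus into contiguous chunks (default 100
documents); `run_adapter` streams each chunk through an external command as
newline-delimited JSON on stdin/stdout, quarantining a failing chunk
(non-zero exit, timeout, malformed output) without aborting the rest, and
recording diagnostics that `write_failures` serializes. Chunked and
unchunked runs of a well-behaved adapter produce identical output — tested,
since chunk boundaries must not leak into results. The `annalign` click CLI
wires these pieces into `ingest-medline`, `ingest-pmc`, `filter`, `synth`,
`run`, `align`, `merge`, `network`, `stats`, and `convert`.

## Verification and measured behavior

- Hirschberg score equals the full-matrix oracle on 1000 seeded random
  pairs (lengths ≤ 200, mixed Latin/Greek/whitespace alphabets) and on a
  hypothesis property; an independent brute-force recursion oracle checks
  the full-matrix scores themselves on short strings.
- On the default synthetic suite (500 docs, seed 42, all kinds at 0.3),
  exact span recovery after realignment is 0.992 (n = 4216) with maximum
  boundary deviation 1; at other seeds the rate lands around 0.99 (e.g.
  0.9891, n = 4115, at the acceptance script's seed 1) with the same
  deviation bound of 1 — the residue is co-optimal-alignment ambiguity at
  span boundaries adjacent to edits, bounded by the overlapping edit length.
- JSON and BioC round-trips are byte/structurally lossless on synthetic
  corpora; brat offsets re-slice exactly.
- Network weight conservation, merge idempotence, and build-order
  invariance hold exactly on a 250-document corpus.

## Limitations

- Alignment is O(nm) time; fine for abstracts and paragraphs (the intended
  unit), slow for whole concatenated full texts — split to paragraphs first.
- Offset maps are per-document and assume the tool did not reorder text;
  block moves are not modeled and would realign as large edits.
- Op-sequence identity with the oracle is guaranteed only up to score
  equality plus gap-run canonicalization; span remapping, not op identity,
  is the supported contract.
- The entity normalizer is overlap-based only; no string similarity or
  ontology expansion.
- `stats --counts` reproduces published percentage tables from their count
  columns; it cannot detect errors in the counts themselves.
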