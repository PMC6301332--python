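import random
from functools import lru_cache

import pytest
from hypothesis import given, settings, strategies as st

from annalign.docmodel import Document, Entity, Relation
from annalign.textalign import (
    DEFAULT_SCORING,
    Alignment,
    OffsetMap,
    Op,
    Scoring,
    UNMAPPED,
    align_full,
    align_hirschberg,
    build_offset_map,
    realign_document,
    remap_span,
)

S = DEFAULT_SCORING


# -- independent oracle: exhaustive enumeration of all global alignments ----

def best_score_bruteforce(a: str, b: str, s: Scoring = S) -> int:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            options.append((s.match if a[i] == b[j] else s.mismatch) + rec(i + 1, j + 1))
        if i < len(a):
            options.append(s.gap + rec(i + 1, j))
        if j < len(b):
            options.append(s.gap + rec(i, j + 1))
        return max(options)

    return rec(0, 0)


def check_ops_valid(al: Alignment, a: str, b: str, s: Scoring = S) -> None:
    i = j = score = 0
    for op in al.ops:
        if op in (Op.MATCH, Op.SUBST):
            assert (a[i] == b[j]) == (op is Op.MATCH)
            score += s.match if op is Op.MATCH else s.mismatch
            i += 1
            j += 1
        elif op is Op.DELETE:
            score += s.gap
            i += 1
        else:
            score += s.gap
            j += 1
    assert (i, j) == (len(a), len(b))
    assert score == al.score


def test_full_identity_alignment():
    al = align_full("AAB", "AAB")
    assert al.ops == [Op.MATCH] * 3 and al.score == 3


def test_full_empty_side():
    al = align_full("A", "")
    assert al.ops == [Op.DELETE] and al.score == -1


def test_full_match_then_substitution():
    # expected score confirmed by exhaustive enumeration of length-2 alignments
    al = align_full("AB", "AC")
    assert al.ops == [Op.MATCH, Op.SUBST]
    assert al.score == best_score_bruteforce("AB", "AC") == 0


@pytest.mark.parametrize("n", range(40))
def test_full_matches_bruteforce_on_short_strings(n):
    rng = random.Random(1000 + n)
    alpha = "ABα "
    a = "".join(rng.choice(alpha) for _ in range(rng.randint(0, 7)))
    b = "".join(rng.choice(alpha) for _ in range(rng.randint(0, 7)))
    al = align_full(a, b)
    assert al.score == best_score_bruteforce(a, b)
    check_ops_valid(al, a, b)


def test_hirschberg_identity():
    x = "phosphorylation of PTEN"
    al = align_hirschberg(x, x)
    assert al.ops == [Op.MATCH] * len(x)
    assert al.score == len(x) * S.match


def test_hirschberg_empty_original():
    al = align_hirschberg("", "abc")
    assert al.ops == [Op.INSERT] * 3 and al.score == 3 * S.gap


def test_hirschberg_scores_match_full_on_seeded_random_pairs():
    rng = random.Random(42)
    alpha = "ACGT- "
    for _ in range(1000):
        a = "".join(rng.choice(alpha) for _ in range(rng.randint(0, 60)))
        b = "".join(rng.choice(alpha) for _ in range(rng.randint(0, 60)))
        full = align_full(a, b)
        hirsch = align_hirschberg(a, b)
        assert hirsch.score == full.score
        check_ops_valid(hirsch, a, b)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.text(alphabet="ACGTαβκ -<>", max_size=200),
    st.text(alphabet="ACGTαβκ -<>", max_size=200),
)
def test_hirschberg_oracle_equivalence_property(a, b):
    assert align_hirschberg(a, b).score == align_full(a, b).score


def test_hirschberg_linear_space_contract():
    rng = random.Random(3)
    for _ in range(50):
        n = rng.randint(0, 300)
        m = rng.randint(0, 300)
        a = "".join(rng.choice("ab c") for _ in range(n))
        b = "".join(rng.choice("ab c") for _ in range(m))
        stats: dict = {}
        align_hirschberg(a, b, stats=stats)
        if stats:
            assert stats["max_buffer_cells"] <= 2 * (min(n, m) + 1)


def test_hirschberg_is_deterministic():
    a, b = "IL-2α activates NF-κB.", "IL-2alpha  activates NF-kappaB ."
    first = align_hirschberg(a, b)
    second = align_hirschberg(a, b)
    assert first.ops == second.ops and first.score == second.score


# -- offset maps ------------------------------------------------------------

def test_offset_map_identity():
    al = align_full("abcd", "abcd")
    assert build_offset_map(al).to_original == [0, 1, 2, 3]


def test_offset_map_insertion_by_construction():
    al = Alignment(ops=[Op.MATCH, Op.INSERT, Op.MATCH], score=1)
    assert build_offset_map(al).to_original == [0, None, 1]


def test_offset_map_ascii_folding_case():
    # "α" folded to "alpha": the substitution anchors at the run start
    al = align_full("IL-2α activates", "IL-2alpha activates")
    m = build_offset_map(al)
    assert m.to_original[4] == 4
    assert m.to_original[5:9] == [None, None, None, None]


def test_offset_map_monotone_on_random_alignments():
    rng = random.Random(11)
    for _ in range(200):
        a = "".join(rng.choice("abα .") for _ in range(rng.randint(0, 40)))
        b = "".join(rng.choice("abα .") for _ in range(rng.randint(0, 40)))
        m = build_offset_map(align_hirschberg(a, b))
        defined = [o for o in m.to_original if o is not None]
        assert defined == sorted(set(defined))  # strictly increasing, injective


def test_remap_identity_span():
    m = OffsetMap.identity(10)
    assert remap_span(3, 7, m) == (3, 7)


def test_remap_shrinks_over_insertions():
    al = align_full("IL-2α activates", "IL-2alpha activates")
    m = build_offset_map(al)
    assert remap_span(0, 9, m) == (0, 5)  # "IL-2alpha" -> "IL-2α"


def test_remap_fully_inserted_span_is_unmapped():
    m = OffsetMap([0, None, None, None, 1])
    assert remap_span(1, 4, m) is UNMAPPED


def test_remap_out_of_bounds_raises():
    with pytest.raises(ValueError):
        remap_span(0, 99, OffsetMap.identity(5))


def test_remapped_disjoint_spans_stay_disjoint_and_ordered():
    rng = random.Random(5)
    a = "the kinase AKT1 phosphorylates the substrate PTEN at Ser380."
    b = "the kinase AKT1 <t> phosphorylates the substrate PTEN at Ser380 ."
    m = build_offset_map(align_hirschberg(a, b))
    spans = [(11, 15), (20, 33), (50, 54)]
    mapped = [remap_span(s, e, m) for s, e in spans]
    for (s1, e1), (s2, e2) in zip(mapped, mapped[1:]):
        assert e1 <= s2


# -- scoring validation ------------------------------------------------------

@pytest.mark.parametrize("kwargs", [dict(match=0), dict(mismatch=1), dict(gap=0)])
def test_invalid_scoring_rejected(kwargs):
    with pytest.raises(ValueError):
        Scoring(**kwargs)


# -- document realignment ----------------------------------------------------

def _tool_doc(text: str, spans: dict[str, tuple[int, int, str]]) -> Document:
    doc = Document(doc_id="d1", text=text)
    for key, (s, e, etype) in spans.items():
        doc.entities[key] = Entity(
            key=key, type=etype, start=s, end=e, surface=text[s:e], tool="t"
        )
    return doc


def test_realign_is_identity_when_texts_match(annotated_doc):
    out = realign_document(annotated_doc.text, annotated_doc)
    assert out == annotated_doc


def test_realign_space_inserted_before_period():
    original = "AKT1 phosphorylates PTEN."
    modified = "AKT1 phosphorylates PTEN ."
    tool = _tool_doc(modified, {"E1": (0, 4, "protein"), "E2": (20, 24, "protein")})
    out = realign_document(original, tool)
    assert (out.entities["E1"].start, out.entities["E1"].end) == (0, 4)
    assert (out.entities["E2"].start, out.entities["E2"].end) == (20, 24)
    assert out.entities["E2"].surface == "PTEN"


def test_realign_drops_unmapped_entity_and_dependent_relation():
    original = "AKT1 binds PTEN."
    modified = "AKT1 <tag> binds PTEN."
    tool = _tool_doc(modified, {"E1": (0, 4, "protein"), "E2": (5, 10, "other")})
    tool.relations["R1"] = Relation(
        key="R1", type="ppi", tool="t", arguments={"a": "E1", "b": "E2"}
    )
    tool.relations["R2"] = Relation(key="R2", type="ppi", tool="t", arguments={"a": "E1"})
    out = realign_document(original, tool)
    assert "E2" not in out.entities  # lies entirely inside inserted text
    assert "R1" not in out.relations  # lost an argument
    assert "R2" in out.relations


def test_realign_remaps_evidence_span():
    original = "AKT1 phosphorylates PTEN."
    modified = "AKT1  phosphorylates PTEN ."
    tool = _tool_doc(modified, {"E1": (0, 4, "protein")})
    tool.relations["R1"] = Relation(
        key="R1", type="phosphorylation", tool="t", arguments={"kinase": "E1"},
        evidence_start=0, evidence_end=len(modified),
    )
    out = realign_document(original, tool)
    rel = out.relations["R1"]
    assert (rel.evidence_start, rel.evidence_end) == (0, len(original))
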