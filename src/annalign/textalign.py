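"""Global text alignment in linear space and annotation offset remapping.

Text-mining tools frequently hand back annotations whose offsets point into a
*modified* copy of the input text: tokenizers insert spaces before
punctuation, markup tags get spliced in, Greek letters are ASCII-folded
("α" becomes "alpha"). To compare or merge results from several tools, every
span must be expressed in the coordinates of the one original text.

This module computes an optimal global alignment between original and
modified text — either with the classic full-matrix dynamic program
(:func:`align_full`, quadratic space, used as the testing oracle) or with
Hirschberg's divide-and-conquer algorithm (:func:`align_hirschberg`, same
optimal score in O(nm) time but only O(min(n, m)) working space) — and turns
the alignment into a per-character offset map used to remap entity spans and
relation evidence spans back onto the original text.

Alignment maximizes a linear-gap score (default match=+1, mismatch=-1,
gap=-1, i.e. Levenshtein-like), is case-sensitive over NFC code points, and
breaks ties deterministically: the traceback prefers MATCH/SUBST over DELETE
over INSERT, and Hirschberg midpoint ties resolve toward the smallest split
index, so outputs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

from .docmodel import Document, Entity, nfc

__all__ = [
    "Op",
    "Scoring",
    "DEFAULT_SCORING",
    "Alignment",
    "OffsetMap",
    "UNALIGNED",
    "UNMAPPED",
    "align_full",
    "align_hirschberg",
    "build_offset_map",
    "remap_span",
    "realign_document",
    "AuditRecord",
]

logger = logging.getLogger(__name__)

#: Cell value for a modified-text position with no original counterpart.
UNALIGNED = None
#: Result of remapping a span that lies entirely inside inserted text.
UNMAPPED = None


class Op(IntEnum):
    """Edit operations of a global alignment (original vs modified text)."""

    MATCH = 0
    SUBST = 1
    INSERT = 2  # character present only in the modified text
    DELETE = 3  # character present only in the original text


@dataclass(frozen=True)
class Scoring:
    """Linear-gap alignment scoring: reward matches, penalize edits."""

    match: int = 1
    mismatch: int = -1
    gap: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch penalty must be <= 0")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")

    def op_score(self, op: Op) -> int:
        if op is Op.MATCH:
            return self.match
        if op is Op.SUBST:
            return self.mismatch
        return self.gap


DEFAULT_SCORING = Scoring()


@dataclass
class Alignment:
    """An edit-operation sequence between original ``a`` and modified ``b``.

    Invariants: MATCH+SUBST+DELETE counts equal ``len(a)``;
    MATCH+SUBST+INSERT counts equal ``len(b)``; ``score`` is the sum of
    per-op scores under the scoring used.
    """

    ops: list[Op]
    score: int


@dataclass
class OffsetMap:
    """Per-character map from modified-text positions to original positions.

    ``to_original[j]`` is the original index aligned to modified position
    ``j``, or :data:`UNALIGNED` for inserted characters. Defined cells are
    strictly increasing and injective.
    """

    to_original: list[Optional[int]]

    def __len__(self) -> int:
        return len(self.to_original)

    @classmethod
    def identity(cls, n: int) -> "OffsetMap":
        return cls(list(range(n)))


def _codes(s: str) -> np.ndarray:
    return np.array([ord(c) for c in s], dtype=np.int64) if s else np.empty(0, dtype=np.int64)


def _fill_row(prev: np.ndarray, a_char: int, bv: np.ndarray, s: Scoring, off: np.ndarray) -> np.ndarray:
    """One DP row. The left-gap recurrence is a max-plus prefix scan:
    cur[j] = max_{k<=j} (t[k] + (j-k)*gap) with t[j] = max(diag, up)."""
    t = np.empty(prev.shape, dtype=np.int64)
    t[0] = prev[0] + s.gap
    sub = np.where(bv == a_char, s.match, s.mismatch)
    np.maximum(prev[:-1] + sub, prev[1:] + s.gap, out=t[1:])
    return np.maximum.accumulate(t - off) + off


def align_full(a: str, b: str, s: Scoring = DEFAULT_SCORING) -> Alignment:
    """Full-matrix Needleman–Wunsch global alignment (quadratic space).

    Serves as the exhaustive oracle for :func:`align_hirschberg`; intended
    for strings up to a few thousand characters. The op sequence is built
    front-to-back over suffix scores, preferring MATCH/SUBST over DELETE
    over INSERT at every tie, so e.g. a substituted character anchors at the
    *start* of an insertion run.
    """
    n, m = len(a), len(b)
    bv = _codes(b)
    # B[i, j] = best score aligning a[i:] vs b[j:]
    off = np.arange(m + 1, dtype=np.int64) * s.gap
    B = np.empty((n + 1, m + 1), dtype=np.int64)
    B[n] = off[::-1]
    for i in range(n - 1, -1, -1):
        t = np.empty(m + 1, dtype=np.int64)
        t[m] = B[i + 1, m] + s.gap
        sub = np.where(bv == ord(a[i]), s.match, s.mismatch)
        np.maximum(B[i + 1, 1:] + sub, B[i + 1, :-1] + s.gap, out=t[:m])
        # right-gap chain: B[i, j] = max_{k >= j} t[k] + (k - j) * gap
        B[i] = (np.maximum.accumulate((t + off)[::-1])[::-1]) - off
    ops: list[Op] = []
    i = j = 0
    while i < n and j < m:
        diag = s.match if a[i] == b[j] else s.mismatch
        if B[i, j] == B[i + 1, j + 1] + diag:
            ops.append(Op.MATCH if a[i] == b[j] else Op.SUBST)
            i += 1
            j += 1
        elif B[i, j] == B[i + 1, j] + s.gap:
            ops.append(Op.DELETE)
            i += 1
        else:
            ops.append(Op.INSERT)
            j += 1
    ops.extend([Op.DELETE] * (n - i))
    ops.extend([Op.INSERT] * (m - j))
    return Alignment(ops=ops, score=int(B[0, 0]))


def _nw_score(a: str, b: str, s: Scoring, stats: Optional[dict]) -> np.ndarray:
    """Last DP row of the global alignment of ``a`` vs ``b`` in two buffers."""
    m = len(b)
    if stats is not None:
        stats["max_buffer_cells"] = max(stats.get("max_buffer_cells", 0), 2 * (m + 1))
    bv = _codes(b)
    off = np.arange(m + 1, dtype=np.int64) * s.gap
    prev = off.copy()
    for ch in a:
        prev = _fill_row(prev, ord(ch), bv, s, off)
    return prev


def _hirschberg_ops(a: str, b: str, s: Scoring, stats: Optional[dict]) -> list[Op]:
    if not a:
        return [Op.INSERT] * len(b)
    if not b:
        return [Op.DELETE] * len(a)
    if len(a) == 1 or len(b) == 1:
        return align_full(a, b, s).ops
    mid = len(a) // 2
    fwd = _nw_score(a[:mid], b, s, stats)
    bwd = _nw_score(a[mid:][::-1], b[::-1], s, stats)
    total = fwd + bwd[::-1]
    split = int(np.argmax(total))  # first maximum -> smallest split index
    return _hirschberg_ops(a[:mid], b[:split], s, stats) + _hirschberg_ops(
        a[mid:], b[split:], s, stats
    )


_TRANSPOSE = {Op.MATCH: Op.MATCH, Op.SUBST: Op.SUBST, Op.INSERT: Op.DELETE, Op.DELETE: Op.INSERT}


def _canonicalize_ops(ops: list[Op], a: str, b: str) -> list[Op]:
    """Rewrite an optimal op sequence into its front-anchored canonical form.

    Divide-and-conquer recombination may emit a co-optimal path where a
    MATCH/SUBST sits at the *end* of a gap run instead of its earliest
    char-compatible position (e.g. "α" vs the inserted "alpha" anchoring at
    the last 'a'). Swapping a diagonal op across a pure INSERT or DELETE run
    keeps the alignment valid and the score unchanged, so this pass bubbles
    each diagonal to the earliest compatible slot — the same position the
    full-matrix front-to-back traceback chooses. Mixed runs (possible only
    when mismatch <= 2*gap) are left untouched.
    """
    out: list[Op] = []
    i = j = 0  # chars of a/b consumed by `out`
    for op in ops:
        if op is Op.INSERT:
            out.append(op)
            j += 1
            continue
        if op is Op.DELETE:
            out.append(op)
            i += 1
            continue
        # diagonal consuming a[i], b[j]: find the trailing pure gap run
        k = 0
        kind = None
        while k < len(out) and out[-1 - k] in (Op.INSERT, Op.DELETE):
            if kind is None:
                kind = out[-1 - k]
            elif out[-1 - k] is not kind:
                kind = None  # mixed run: do not rewrite
                break
            k += 1
        pos = len(out)
        if kind is Op.INSERT and k:
            run_chars = b[j - k : j]
            want_match = a[i] == b[j]
            for p in range(k):
                if (run_chars[p] == a[i]) == want_match:
                    pos = len(out) - k + p
                    break
        elif kind is Op.DELETE and k:
            run_chars = a[i - k : i]
            want_match = a[i] == b[j]
            for p in range(k):
                if (run_chars[p] == b[j]) == want_match:
                    pos = len(out) - k + p
                    break
        out.insert(pos, op)
        i += 1
        j += 1
    return out


def align_hirschberg(
    a: str, b: str, s: Scoring = DEFAULT_SCORING, stats: Optional[dict] = None
) -> Alignment:
    """Optimal global alignment in linear space (Hirschberg's algorithm).

    Produces the same optimal score as :func:`align_full` on every input,
    using scoring-pass buffers bounded by ``2 * (min(len(a), len(b)) + 1)``
    cells. Pass a ``stats`` dict to record ``max_buffer_cells`` for
    instrumentation.

    The strings are oriented so the DP rows run over the shorter one; the
    resulting op sequence is deterministic for given inputs and scoring.
    """
    if len(b) > len(a):
        ops = [_TRANSPOSE[op] for op in _hirschberg_ops(b, a, s, stats)]
    else:
        ops = _hirschberg_ops(a, b, s, stats)
    ops = _canonicalize_ops(ops, a, b)
    score = 0
    i = j = 0
    for op in ops:
        score += s.op_score(op)
        if op in (Op.MATCH, Op.SUBST):
            i += 1
            j += 1
        elif op is Op.DELETE:
            i += 1
        else:
            j += 1
    assert i == len(a) and j == len(b)
    return Alignment(ops=ops, score=score)


def build_offset_map(al: Alignment) -> OffsetMap:
    """Induce the modified→original position map from an alignment.

    Modified positions consumed by MATCH/SUBST map to the original index
    consumed by the same op; positions consumed by INSERT are UNALIGNED.
    """
    to_original: list[Optional[int]] = []
    i = 0
    for op in al.ops:
        if op in (Op.MATCH, Op.SUBST):
            to_original.append(i)
            i += 1
        elif op is Op.INSERT:
            to_original.append(UNALIGNED)
        else:  # DELETE consumes an original char with no modified counterpart
            i += 1
    return OffsetMap(to_original)


def remap_span(start: int, end: int, m: OffsetMap) -> Optional[tuple[int, int]]:
    """Map a modified-text span onto the original text.

    Returns ``(start', end')`` spanning from the smallest to the largest
    aligned original position inside ``[start, end)`` — spans shrink across
    insertions, so the mapped surface is always a substring of the original —
    or :data:`UNMAPPED` when no position in the span is aligned.
    """
    if not (0 <= start < end <= len(m.to_original)):
        raise ValueError(f"span ({start}, {end}) out of bounds for map of length {len(m)}")
    defined = [o for o in m.to_original[start:end] if o is not UNALIGNED]
    if not defined:
        return UNMAPPED
    return defined[0], defined[-1] + 1


@dataclass
class AuditRecord:
    """One remapping outcome for the per-entity audit log."""

    doc_id: str
    kind: str  # "entity" | "relation"
    key: str
    old_span: tuple[int, int]
    new_span: Optional[tuple[int, int]]
    status: str  # "remapped" | "unmapped-dropped" | "argument-dropped"


def realign_document(
    original_text: str,
    tool_doc: Document,
    s: Scoring = DEFAULT_SCORING,
    audit: Optional[list[AuditRecord]] = None,
) -> Document:
    """Remap a tool's annotations from its modified text onto the original.

    Aligns ``original_text`` against ``tool_doc.text`` with Hirschberg's
    algorithm and rewrites every entity span and relation evidence span in
    original coordinates, re-slicing surface strings from the original text.
    Entities whose whole span falls inside inserted text are dropped (and
    logged); relations that lose an argument entity are dropped likewise.
    Degradation is never fatal.
    """
    original = nfc(original_text)
    out = Document(doc_id=tool_doc.doc_id, text=original, properties=dict(tool_doc.properties))
    if tool_doc.text == original:
        offmap = OffsetMap.identity(len(original))
    else:
        offmap = build_offset_map(align_hirschberg(original, tool_doc.text, s))

    dropped: set[str] = set()
    for key, ent in tool_doc.entities.items():
        mapped = remap_span(ent.start, ent.end, offmap)
        if mapped is UNMAPPED:
            dropped.add(key)
            logger.info("doc %s: entity %s %r unmapped, dropped", out.doc_id, key, ent.surface)
            if audit is not None:
                audit.append(
                    AuditRecord(out.doc_id, "entity", key, (ent.start, ent.end), None, "unmapped-dropped")
                )
            continue
        ns, ne = mapped
        out.entities[key] = Entity(
            key=key,
            type=ent.type,
            start=ns,
            end=ne,
            surface=original[ns:ne],
            tool=ent.tool,
            norm_ids=list(ent.norm_ids),
        )
        if audit is not None:
            audit.append(
                AuditRecord(out.doc_id, "entity", key, (ent.start, ent.end), (ns, ne), "remapped")
            )
    for key, rel in tool_doc.relations.items():
        lost = [k for k in rel.arguments.values() if k in dropped or k not in tool_doc.entities]
        if lost:
            logger.info(
                "doc %s: relation %s dropped (lost arguments %s)", out.doc_id, key, lost
            )
            if audit is not None:
                span = (rel.evidence_start or 0, rel.evidence_end or 0)
                audit.append(AuditRecord(out.doc_id, "relation", key, span, None, "argument-dropped"))
            continue
        new_rel = rel.copy()
        if rel.evidence_start is not None and rel.evidence_end is not None:
            mapped = remap_span(rel.evidence_start, rel.evidence_end, offmap)
            if mapped is UNMAPPED:
                new_rel.evidence_start = new_rel.evidence_end = None
            else:
                new_rel.evidence_start, new_rel.evidence_end = mapped
        out.relations[key] = new_rel
    return out
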