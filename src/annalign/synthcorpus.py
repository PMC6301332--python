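"""Synthetic corpora, tool-style text perturbations and mock tool outputs.

Real extraction tools are large external systems; what this package needs to
exercise is everything *around* them: text that carries plantable entity
mentions and relations, tool views of that text mutated the way NLP
pipelines actually mutate it (spaces inserted before punctuation, markup
tags spliced in, Greek letters ASCII-folded, whitespace collapsed, curly
quotes straightened), and tool outputs whose offsets point into the mutated
text. Every perturbation maintains its exact position map by construction,
so realignment can be scored against known ground truth.

The generator emulates the *structure* of biomedical abstracts — short
declarative sentences with gene/miRNA/disease/drug mentions, trigger words
and one relation per sentence across four relation vocabularies
(phosphorylation, phosphorylation-dependent PPI, miRNA–gene targeting, drug
response) — not their linguistic fluency. All randomness flows from one
seeded generator per call; no global random state is touched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .docmodel import Document, Entity, Relation
from .integrate import NerAnnotation
from .textalign import OffsetMap

__all__ = [
    "PERTURBATION_KINDS",
    "PerturbationSpec",
    "PlantedTruth",
    "generate_corpus",
    "perturb",
    "simulate_tool_output",
    "ner_annotations_for",
    "TOOL_FOR_RELATION",
]

# Greek letters folded to names by tool pipelines; covers the symbols common
# in gene/protein nomenclature.
GREEK_TO_NAME = {"α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "κ": "kappa"}
_PUNCT = ".,;:!?"
_QUOTES = {"‘": "'", "’": "'", "“": '"', "”": '"'}

PERTURBATION_KINDS = (
    "insert_space_before_punct",
    "greek_to_name",
    "insert_tag",
    "collapse_whitespace",
    "ascii_quote_substitution",
)


@dataclass(frozen=True)
class PerturbationSpec:
    """One text mutation: which kind, how often per opportunity, which seed."""

    kind: str
    rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not (0.0 <= self.rate <= 1.0):
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")


# Each kind emits (char, index-into-its-input-text | None) pairs; None marks
# inserted characters. Input characters may also be dropped (deletions).
def _emit(text: str, kind: str, rate: float, rng: random.Random) -> list[tuple[str, Optional[int]]]:
    out: list[tuple[str, Optional[int]]] = []
    if kind == "insert_space_before_punct":
        for i, ch in enumerate(text):
            if ch in _PUNCT and i > 0 and not text[i - 1].isspace() and rng.random() < rate:
                out.append((" ", None))
            out.append((ch, i))
    elif kind == "greek_to_name":
        for i, ch in enumerate(text):
            name = GREEK_TO_NAME.get(ch)
            if name is not None and rng.random() < rate:
                out.append((name[0], i))
                out.extend((c, None) for c in name[1:])
            else:
                out.append((ch, i))
    elif kind == "insert_tag":
        for i, ch in enumerate(text):
            out.append((ch, i))
            if ch == " " and rng.random() < rate:
                out.extend((c, None) for c in "<t> ")
    elif kind == "collapse_whitespace":
        prev_space = False
        for i, ch in enumerate(text):
            if ch == " " and prev_space and rng.random() < rate:
                continue  # drop the redundant space
            out.append((ch, i))
            prev_space = ch == " "
    elif kind == "ascii_quote_substitution":
        for i, ch in enumerate(text):
            repl = _QUOTES.get(ch)
            if repl is not None and rng.random() < rate:
                out.append((repl, i))
            else:
                out.append((ch, i))
    else:  # pragma: no cover - guarded by PerturbationSpec
        raise ValueError(kind)
    return out


def perturb(text: str, specs: Sequence[PerturbationSpec]) -> tuple[str, OffsetMap]:
    """Apply perturbations in order, maintaining the exact position map.

    Returns the modified text and the ground-truth map from modified
    positions back to the original text (None cells for inserted
    characters). Applying specs sequentially composes their maps, so the
    result is exactly what an alignment of the two texts should recover.
    """
    current = text
    total: list[Optional[int]] = list(range(len(text)))
    for spec in specs:
        rng = random.Random(spec.seed)
        emitted = _emit(current, spec.kind, spec.rate, rng)
        current = "".join(ch for ch, _ in emitted)
        total = [total[idx] if idx is not None else None for _, idx in emitted]
    return current, OffsetMap(total)


# ---------------------------------------------------------------------------
# corpus generation

# (surface, NCBI gene ID, UniProt accession); Greek-lettered names included
# so the ASCII-folding perturbation has real targets.
_PROTEINS = [
    ("PTEN", "5728", "P60484"),
    ("TP53", "7157", "P04637"),
    ("AKT1", "207", "P31749"),
    ("SATB1", "6304", "Q01826"),
    ("CDK2", "1017", "P24941"),
    ("MAPK1", "5594", "P28482"),
    ("PDCD4", "27250", "Q53EL6"),
    ("STAT3", "6774", "P40763"),
    ("GSK3β", "2932", "P49841"),
    ("CK2α", "1457", "P68400"),
    ("NF-κB", "4790", "P19838"),
    ("IκBα", "4792", "P25963"),
    ("TGF-β1", "7040", "P01137"),
    ("ERα", "2099", "P03372"),
]
_MIRNAS = [
    ("miR-21", "406991"),
    ("miR-155", "406947"),
    ("miR-34a", "407040"),
    ("let-7a", "406881"),
]
_DISEASES = [
    ("breast cancer", "1612"),
    ("gastric cancer", "10534"),
    ("osteosarcoma", "3347"),
    ("colorectal cancer", "9256"),
]
_DRUGS = [
    ("vincristine", "D014750"),
    ("tamoxifen", "D013629"),
    ("cisplatin", "D002945"),
    ("doxorubicin", "D004317"),
]
_SITES = ["Ser473", "Thr308", "Tyr705", "Ser15", "Thr202"]
_OUTCOMES = ["resistance", "sensitivity", "poor response"]

#: Which mock tool owns each relation vocabulary.
TOOL_FOR_RELATION = {
    "phosphorylation": "mock_rlims",
    "ppi": "mock_efip",
    "mirna_target": "mock_mirtex",
    "drug_response": "mock_egard",
}


@dataclass
class PlantedTruth:
    """Ground truth for one generated document: the planted annotations."""

    entities: dict[str, Entity] = field(default_factory=dict)
    relations: dict[str, Relation] = field(default_factory=dict)


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc = Document(doc_id=doc_id, text="")
        self._n_ent = 0
        self._n_rel = 0

    def lit(self, s: str) -> None:
        self.doc.text += s

    def ent(self, surface: str, etype: str, norm_ids: list[tuple[str, str]], tool: str) -> str:
        self._n_ent += 1
        key = f"E{self._n_ent}"
        start = len(self.doc.text)
        self.doc.text += surface
        self.doc.entities[key] = Entity(
            key=key,
            type=etype,
            start=start,
            end=start + len(surface),
            surface=surface,
            tool=tool,
            norm_ids=list(norm_ids),
        )
        return key

    def rel(self, rtype: str, args: dict[str, str], ev_start: int, tool: str) -> None:
        self._n_rel += 1
        key = f"R{self._n_rel}"
        self.doc.relations[key] = Relation(
            key=key,
            type=rtype,
            tool=tool,
            arguments=args,
            evidence_start=ev_start,
            evidence_end=len(self.doc.text),
        )


def _sent_phosphorylation(b: _DocBuilder, rng: random.Random) -> None:
    tool = TOOL_FOR_RELATION["phosphorylation"]
    kin, sub = rng.sample(_PROTEINS, 2)
    site = rng.choice(_SITES)
    start = len(b.doc.text)
    k = b.ent(kin[0], "protein", [("NCBI_gene", kin[1]), ("UniProt", kin[2])], tool)
    b.lit(" phosphorylates ")
    s = b.ent(sub[0], "protein", [("NCBI_gene", sub[1]), ("UniProt", sub[2])], tool)
    b.lit(" at ")
    st = b.ent(site, "other", [], tool)
    b.lit(".")
    b.rel("phosphorylation", {"kinase": k, "substrate": s, "site": st}, start, tool)


def _sent_ppi(b: _DocBuilder, rng: random.Random) -> None:
    tool = TOOL_FOR_RELATION["ppi"]
    p1, p2 = rng.sample(_PROTEINS, 2)
    start = len(b.doc.text)
    b.lit("Phosphorylation of ")
    k1 = b.ent(p1[0], "protein", [("NCBI_gene", p1[1]), ("UniProt", p1[2])], tool)
    b.lit(" enhances its interaction with ")
    k2 = b.ent(p2[0], "protein", [("NCBI_gene", p2[1]), ("UniProt", p2[2])], tool)
    b.lit(".")
    b.rel("ppi", {"protein1": k1, "protein2": k2}, start, tool)


def _sent_mirna(b: _DocBuilder, rng: random.Random) -> None:
    tool = TOOL_FOR_RELATION["mirna_target"]
    mir = rng.choice(_MIRNAS)
    gene = rng.choice(_PROTEINS)
    start = len(b.doc.text)
    m = b.ent(mir[0], "mirna", [("NCBI_gene", mir[1])], tool)
    b.lit(" directly targets ")
    g = b.ent(gene[0], "gene", [("NCBI_gene", gene[1]), ("UniProt", gene[2])], tool)
    b.lit(" and represses its expression.")
    b.rel("mirna_target", {"mirna": m, "target": g}, start, tool)


def _sent_drug(b: _DocBuilder, rng: random.Random) -> None:
    tool = TOOL_FOR_RELATION["drug_response"]
    gene = rng.choice(_PROTEINS)
    drug = rng.choice(_DRUGS)
    disease = rng.choice(_DISEASES)
    outcome = rng.choice(_OUTCOMES)
    start = len(b.doc.text)
    b.lit("Patients’ ")
    d = b.ent(disease[0], "disease", [("DOID", disease[1])], tool)
    b.lit(" tumors with ")
    g = b.ent(gene[0], "gene", [("NCBI_gene", gene[1]), ("UniProt", gene[2])], tool)
    b.lit(" overexpression showed ")
    o = b.ent(outcome, "outcome", [], tool)
    b.lit(" to ")
    dr = b.ent(drug[0], "chemical", [("MESH", drug[1])], tool)
    b.lit(".")
    b.rel(
        "drug_response", {"gene": g, "drug": dr, "disease": d, "outcome": o}, start, tool
    )


_TEMPLATES: list[Callable[[_DocBuilder, random.Random], None]] = [
    _sent_phosphorylation,
    _sent_ppi,
    _sent_mirna,
    _sent_drug,
]


def generate_corpus(n_docs: int, seed: int) -> list[tuple[Document, PlantedTruth]]:
    """Generate ``n_docs`` annotated documents with known ground truth.

    Deterministic for a given seed: each document holds 2–4 template
    sentences, each planting one relation (and its argument entities) from
    one of the four relation vocabularies. The returned truth records every
    planted span, identifier and relation; the document carries the same
    annotations with per-relation tool provenance.
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    rng = random.Random(seed)
    out: list[tuple[Document, PlantedTruth]] = []
    for i in range(n_docs):
        b = _DocBuilder(doc_id=str(9_000_000 + i))
        n_sent = rng.randint(2, 4)
        for si in range(n_sent):
            if si:
                b.lit(" ")
            rng.choice(_TEMPLATES)(b, rng)
        truth = PlantedTruth(
            entities={k: e.copy() for k, e in b.doc.entities.items()},
            relations={k: r.copy() for k, r in b.doc.relations.items()},
        )
        out.append((b.doc, truth))
    return out


def ner_annotations_for(doc: Document) -> list[NerAnnotation]:
    """Derive PubTator-style NER annotations from a gold document.

    Emits one annotation per planted entity with a normalization ID (first
    identifier pair), mimicking the independent NER/normalization layer used
    by the post-processing step.
    """
    out = []
    for ent in doc.entities.values():
        if not ent.norm_ids:
            continue
        source, ident = ent.norm_ids[0]
        out.append(
            NerAnnotation(
                doc_id=doc.doc_id,
                start=ent.start,
                end=ent.end,
                type=ent.type,
                source=source,
                identifier=ident,
            )
        )
    return out


def _invert(m: OffsetMap) -> dict[int, int]:
    return {orig: j for j, orig in enumerate(m.to_original) if orig is not None}


def simulate_tool_output(
    doc: Document,
    truth: PlantedTruth,
    specs: Sequence[PerturbationSpec],
    tool: Optional[str] = None,
) -> Document:
    """Mock one tool's output: perturbed text with offsets in its coordinates.

    Restricts annotations to the given ``tool`` (all when None), perturbs
    the document text, and re-expresses every entity span and evidence span
    in perturbed coordinates via the ground-truth map — exactly what a real
    tool that mutates its input hands back. Normalization IDs are stripped:
    attaching identifiers is the job of the post-processing stage.
    """
    mtext, mmap = perturb(doc.text, specs)
    inv = _invert(mmap)

    def map_span(start: int, end: int) -> Optional[tuple[int, int]]:
        cells = [inv[o] for o in range(start, end) if o in inv]
        if not cells:
            return None
        return min(cells), max(cells) + 1

    out = Document(doc_id=doc.doc_id, text=mtext, properties=dict(doc.properties))
    kept_relations = {
        k: r
        for k, r in truth.relations.items()
        if tool is None or r.tool == tool
    }
    needed = {ek for r in kept_relations.values() for ek in r.arguments.values()}
    dropped: set[str] = set()
    for key in sorted(needed):
        ent = truth.entities[key]
        span = map_span(ent.start, ent.end)
        if span is None:
            dropped.add(key)
            continue
        s, e = span
        out.entities[key] = Entity(
            key=key,
            type=ent.type,
            start=s,
            end=e,
            surface=mtext[s:e],
            tool=tool or ent.tool,
            norm_ids=[],
        )
    for key, rel in kept_relations.items():
        if any(ek in dropped for ek in rel.arguments.values()):
            continue
        ev = None
        if rel.evidence_start is not None and rel.evidence_end is not None:
            ev = map_span(rel.evidence_start, rel.evidence_end)
        out.relations[key] = Relation(
            key=key,
            type=rel.type,
            tool=tool or rel.tool,
            arguments=dict(rel.arguments),
            evidence_start=None if ev is None else ev[0],
            evidence_end=None if ev is None else ev[1],
        )
    return out
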