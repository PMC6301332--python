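"""Corpus ingestion and interchange formats.

Readers turn Medline citation XML and PMC JATS full-text XML into the
package's document model: one document per abstract (title + blank line +
abstract body), and one document per paragraph of a full-text article, with
figure and table captions extracted as standalone paragraphs and the section
type kept as a document property. Trigger-word filtering selects the subset
of documents a rule-based extractor could possibly fire on (e.g. the
``phospho*`` pre-filter for phosphorylation mining).

Writers and readers for BioC XML and brat standoff make annotated documents
interoperable with the wider text-mining ecosystem. BioC locations use
offset+length in the same 0-based code-point convention as internal spans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

from lxml import etree

from .docmodel import Document, Entity, Relation, nfc, validate_document

__all__ = [
    "SECTION_TYPES",
    "ParagraphRef",
    "parse_medline_xml",
    "parse_pmc_jats",
    "filter_by_trigger",
    "write_bioc",
    "read_bioc",
    "write_brat",
    "BiocValidationError",
]

logger = logging.getLogger(__name__)

SECTION_TYPES = (
    "title",
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "conclusion",
    "figure_caption",
    "table_caption",
    "other",
)


@dataclass(frozen=True)
class ParagraphRef:
    """Position of one paragraph within a PMC article."""

    pmcid: str
    paragraph_index: int
    section_type: str

    def doc_id(self) -> str:
        return f"{self.pmcid}.{self.paragraph_index}"


class BiocValidationError(ValueError):
    """BioC annotation offsets inconsistent with the passage text."""


def _clean_text(el: etree._Element) -> str:
    return nfc(" ".join("".join(el.itertext()).split()))


def _to_tree(stream: Union[str, bytes, IO]) -> etree._Element:
    if isinstance(stream, str):
        stream = stream.encode("utf-8")
    if isinstance(stream, bytes):
        return etree.fromstring(stream)
    return etree.parse(stream).getroot()


# ---------------------------------------------------------------------------
# Medline


def parse_medline_xml(stream: Union[str, bytes, IO]) -> list[Document]:
    """Parse Medline/PubMed citation XML into one document per citation.

    The document text is the article title, a blank line, then the abstract
    (AbstractText sections joined, labels dropped). ``doc_id`` is the PMID;
    journal and year are recorded as properties when present.
    """
    try:
        root = _to_tree(stream)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed Medline XML: {exc}") from exc
    docs: list[Document] = []
    for idx, citation in enumerate(root.iter("MedlineCitation")):
        pmid_el = citation.find("PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            raise ValueError(f"citation #{idx}: missing PMID")
        pmid = pmid_el.text.strip()
        article = citation.find("Article")
        if article is None:
            raise ValueError(f"citation #{idx} (PMID {pmid}): missing Article element")
        title_el = article.find("ArticleTitle")
        title = _clean_text(title_el) if title_el is not None else ""
        abstract_parts = [
            _clean_text(t) for t in article.findall("Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abstract_parts if p)
        props: dict[str, str] = {}
        journal = article.find("Journal/Title")
        if journal is not None and journal.text:
            props["journal"] = journal.text.strip()
        year = article.find("Journal/JournalIssue/PubDate/Year")
        if year is not None and year.text:
            props["year"] = year.text.strip()
        if abstract:
            text = f"{title}\n\n{abstract}" if title else abstract
            props["abstract_present"] = "true"
        else:
            text = title
            props["abstract_present"] = "false"
        docs.append(Document(doc_id=pmid, text=text, properties=props))
    return docs


# ---------------------------------------------------------------------------
# PMC JATS

_SEC_TYPE_KEYWORDS = (
    ("intro", "introduction"),
    ("background", "introduction"),
    ("method", "methods"),
    ("material", "methods"),
    ("result", "results"),
    ("discussion", "discussion"),
    ("conclusion", "conclusion"),
)


def _section_type_for(el: etree._Element) -> str:
    """Nearest-ancestor section type: sec-type attribute, else title keyword."""
    for sec in el.iterancestors("sec"):
        hint = (sec.get("sec-type") or "").lower()
        if not hint:
            title = sec.find("title")
            hint = _clean_text(title).lower() if title is not None else ""
        for keyword, stype in _SEC_TYPE_KEYWORDS:
            if keyword in hint:
                return stype
    return "other"


def parse_pmc_jats(
    stream: Union[str, bytes, IO], section_types: Optional[Sequence[str]] = None
) -> list[Document]:
    """Split a JATS full-text article into one document per paragraph.

    Body paragraphs and figure/table captions become separate documents,
    numbered by original order; ``doc_id`` is ``<PMCID>.<paragraph_index>``
    and properties carry pmcid, paragraph_index and section_type. Captions
    get section type ``figure_caption``/``table_caption`` regardless of the
    enclosing section. ``section_types`` restricts the output to the given
    types (the paragraph numbering is assigned before filtering, so indices
    remain stable).
    """
    try:
        root = _to_tree(stream)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed JATS XML: {exc}") from exc
    pmcid = "PMC_unknown"
    for aid in root.iter("article-id"):
        if aid.get("pub-id-type") == "pmc" and aid.text:
            pmcid = aid.text.strip()
            if not pmcid.upper().startswith("PMC"):
                pmcid = "PMC" + pmcid
            break
    body = root.find("body")
    paragraphs: list[tuple[str, str]] = []  # (section_type, text)
    if body is not None:
        for el in body.iter():
            if el.tag == "p":
                # caption paragraphs are emitted with their enclosing caption
                if any(a.tag == "caption" for a in el.iterancestors()):
                    continue
                text = _clean_text(el)
                if text:
                    paragraphs.append((_section_type_for(el), text))
            elif el.tag == "caption":
                parent = el.getparent()
                kind = "table_caption" if parent is not None and parent.tag == "table-wrap" else "figure_caption"
                text = _clean_text(el)
                if text:
                    paragraphs.append((kind, text))
    if not paragraphs:
        logger.warning("article %s: empty body, no paragraphs extracted", pmcid)
    docs: list[Document] = []
    for index, (stype, text) in enumerate(paragraphs):
        if section_types is not None and stype not in section_types:
            continue
        ref = ParagraphRef(pmcid=pmcid, paragraph_index=index, section_type=stype)
        docs.append(
            Document(
                doc_id=ref.doc_id(),
                text=text,
                properties={
                    "parent_doc": pmcid,
                    "paragraph_index": str(index),
                    "section_type": stype,
                },
            )
        )
    return docs


# ---------------------------------------------------------------------------
# trigger-word pre-filtering


def filter_by_trigger(docs: Iterable[Document], pattern: str) -> list[Document]:
    """Keep documents whose text matches ``pattern`` (case-insensitive).

    Mirrors the trigger-word pre-filter used before running rule-based
    extractors: text without the trigger cannot produce output and is safe
    to drop. Order is preserved; filtering is idempotent.
    """
    try:
        rx = re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid trigger pattern {pattern!r}: {exc}") from exc
    return [doc for doc in docs if rx.search(doc.text)]


# ---------------------------------------------------------------------------
# BioC XML


def write_bioc(docs: Sequence[Document]) -> str:
    """Serialize documents as a BioC XML collection (one passage each).

    Entities become annotations with offset+length locations; relations
    become BioC relations with role-labelled node references. Normalization
    IDs and evidence spans ride in infons, so :func:`read_bioc` can invert
    the conversion losslessly.
    """
    coll = etree.Element("collection")
    etree.SubElement(coll, "source").text = "annalign"
    etree.SubElement(coll, "date").text = ""
    etree.SubElement(coll, "key").text = "annalign.key"
    for doc in docs:
        violations = validate_document(doc)
        if violations:
            raise ValueError(f"invalid document {doc.doc_id!r}: {violations[0]}")
        d = etree.SubElement(coll, "document")
        etree.SubElement(d, "id").text = doc.doc_id
        for k, v in doc.properties.items():
            infon = etree.SubElement(d, "infon", key=f"prop:{k}")
            infon.text = v
        p = etree.SubElement(d, "passage")
        etree.SubElement(p, "offset").text = "0"
        etree.SubElement(p, "text").text = doc.text
        for key in sorted(doc.entities):
            ent = doc.entities[key]
            a = etree.SubElement(p, "annotation", id=key)
            etree.SubElement(a, "infon", key="type").text = ent.type
            etree.SubElement(a, "infon", key="tool").text = ent.tool
            for source, ident in ent.norm_ids:
                etree.SubElement(a, "infon", key=f"norm:{source}").text = ident
            etree.SubElement(
                a, "location", offset=str(ent.start), length=str(ent.end - ent.start)
            )
            etree.SubElement(a, "text").text = ent.surface
        for key in sorted(doc.relations):
            rel = doc.relations[key]
            r = etree.SubElement(p, "relation", id=key)
            etree.SubElement(r, "infon", key="type").text = rel.type
            etree.SubElement(r, "infon", key="tool").text = rel.tool
            if rel.evidence_start is not None:
                etree.SubElement(r, "infon", key="evidence_start").text = str(rel.evidence_start)
                etree.SubElement(r, "infon", key="evidence_end").text = str(rel.evidence_end)
            for role in sorted(rel.arguments):
                etree.SubElement(r, "node", refid=rel.arguments[role], role=role)
    return etree.tostring(
        coll, encoding="unicode", pretty_print=True, doctype=None
    )


def read_bioc(stream: Union[str, bytes, IO]) -> list[Document]:
    """Parse a BioC XML collection back into documents (inverse of write)."""
    try:
        root = _to_tree(stream)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed BioC XML: {exc}") from exc
    docs: list[Document] = []
    for d in root.iter("document"):
        doc_id = (d.findtext("id") or "").strip()
        props: dict[str, str] = {}
        for infon in d.findall("infon"):
            key = infon.get("key", "")
            if key.startswith("prop:"):
                props[key[5:]] = infon.text or ""
        passage = d.find("passage")
        if passage is None:
            raise ValueError(f"BioC document {doc_id!r}: missing passage")
        text = passage.findtext("text") or ""
        doc = Document(doc_id=doc_id, text=text, properties=props)
        for a in passage.findall("annotation"):
            key = a.get("id") or ""
            infons = {i.get("key", ""): (i.text or "") for i in a.findall("infon")}
            loc = a.find("location")
            if loc is None:
                raise ValueError(f"BioC annotation {key!r}: missing location")
            start = int(loc.get("offset"))
            length = int(loc.get("length"))
            surface = a.findtext("text") or ""
            if text[start : start + length] != surface:
                raise BiocValidationError(
                    f"document {doc_id!r} annotation {key!r}: location "
                    f"({start}, +{length}) does not slice to {surface!r}"
                )
            norm_ids = [
                (k[5:], v) for k, v in infons.items() if k.startswith("norm:")
            ]
            doc.entities[key] = Entity(
                key=key,
                type=infons.get("type", "other"),
                start=start,
                end=start + length,
                surface=surface,
                tool=infons.get("tool", ""),
                norm_ids=norm_ids,
            )
        for r in passage.findall("relation"):
            key = r.get("id") or ""
            infons = {i.get("key", ""): (i.text or "") for i in r.findall("infon")}
            args = {n.get("role", ""): n.get("refid", "") for n in r.findall("node")}
            es = infons.get("evidence_start")
            ee = infons.get("evidence_end")
            doc.relations[key] = Relation(
                key=key,
                type=infons.get("type", ""),
                tool=infons.get("tool", ""),
                arguments=args,
                evidence_start=None if es is None else int(es),
                evidence_end=None if ee is None else int(ee),
            )
        docs.append(doc)
    return docs


# ---------------------------------------------------------------------------
# brat standoff


def write_brat(doc: Document) -> tuple[str, str]:
    """Render a document as a brat standoff ``(.txt, .ann)`` pair.

    Entities become T-lines and relations R-lines, numbered in key-sorted
    order; every emitted offset re-slices the .txt content to the recorded
    surface string.
    """
    violations = validate_document(doc)
    if violations:
        raise ValueError(f"invalid document {doc.doc_id!r}: {violations[0]}")
    lines: list[str] = []
    t_index: dict[str, str] = {}
    for n, key in enumerate(sorted(doc.entities), start=1):
        ent = doc.entities[key]
        t_index[key] = f"T{n}"
        lines.append(f"T{n}\t{ent.type} {ent.start} {ent.end}\t{ent.surface}")
    for n, key in enumerate(sorted(doc.relations), start=1):
        rel = doc.relations[key]
        args = " ".join(
            f"{role}:{t_index[rel.arguments[role]]}" for role in sorted(rel.arguments)
        )
        lines.append(f"R{n}\t{rel.type} {args}")
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return doc.text, ann
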