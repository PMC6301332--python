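"""Document-centric annotation data model and its canonical JSON serialization.

The unit of work everywhere in this package is a *document*: one Medline
abstract, or one paragraph of a PMC full-text article. A document carries its
text plus standoff annotations — typed entity spans and n-ary relations over
them — keyed in hash maps so that records from different text-mining tools can
be addressed, merged and deduplicated without renumbering.

Offsets are 0-based, half-open and counted in Unicode code points; text is
NFC-normalized on ingest so that equivalent Unicode encodings yield identical
offsets. Serialization is canonical (sorted keys except the ordered
``properties`` map, UTF-8, minimal separators), so structurally equal
documents produce identical bytes.
"""

from __future__ import annotations

import io
import json
import unicodedata
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Union

__all__ = [
    "ENTITY_TYPES",
    "Entity",
    "Relation",
    "Document",
    "Violation",
    "DocumentValidationError",
    "DocumentParseError",
    "validate_document",
    "read_document_json",
    "write_document_json",
    "read_document_collection",
    "write_document_collection",
]

#: Entity types understood by the model. ``other`` is the catch-all for
#: tool-specific argument types (e.g. phosphorylation sites).
ENTITY_TYPES = frozenset(
    {
        "gene",
        "protein",
        "mirna",
        "disease",
        "chemical",
        "mutation",
        "trigger",
        "outcome",
        "other",
    }
)


class DocumentParseError(ValueError):
    """Raised when a stream does not contain well-formed document JSON."""


class DocumentValidationError(ValueError):
    """Raised when a document violates a model invariant.

    Carries the list of :class:`Violation` descriptors that were detected.
    """

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


@dataclass(frozen=True)
class Violation:
    """One violated invariant: where (entity/relation key) and which rule."""

    scope: str  # "document" | "entity" | "relation"
    key: str  # offending entity/relation key, or the document id
    rule: str  # short rule identifier, e.g. "surface-mismatch"
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.scope} {self.key!r}: {self.rule} ({self.message})"


@dataclass
class Entity:
    """A typed text span with provenance and zero or more database identifiers.

    ``norm_ids`` holds ``(source, identifier)`` pairs, e.g.
    ``("NCBI_gene", "5728")`` or ``("UniProt", "P60484")``. ``tool`` names the
    producing text-mining tool; after multi-tool merging it may be a
    comma-joined list of tool names.
    """

    key: str
    type: str
    start: int
    end: int
    surface: str
    tool: str
    norm_ids: list[tuple[str, str]] = field(default_factory=list)

    def copy(self) -> "Entity":
        return replace(self, norm_ids=list(self.norm_ids))


@dataclass
class Relation:
    """A typed n-ary link over entity keys with role labels.

    ``arguments`` maps role names (``kinase``, ``substrate``, ``mirna``,
    ``target``, ``drug`` ...) to entity keys of the owning document. The
    optional evidence span addresses the supporting sentence or passage in
    the document text.
    """

    key: str
    type: str
    tool: str
    arguments: dict[str, str]
    evidence_start: int | None = None
    evidence_end: int | None = None

    def copy(self) -> "Relation":
        return replace(self, arguments=dict(self.arguments))


@dataclass
class Document:
    """One abstract or paragraph with its standoff annotations.

    ``properties`` is an *ordered* string map (section type, paragraph index,
    parent article id ...); its order is preserved through serialization.
    """

    doc_id: str
    text: str
    properties: dict[str, str] = field(default_factory=dict)
    entities: dict[str, Entity] = field(default_factory=dict)
    relations: dict[str, Relation] = field(default_factory=dict)

    def copy(self) -> "Document":
        return Document(
            doc_id=self.doc_id,
            text=self.text,
            properties=dict(self.properties),
            entities={k: e.copy() for k, e in self.entities.items()},
            relations={k: r.copy() for k, r in self.relations.items()},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Document):
            return NotImplemented
        return (
            self.doc_id == other.doc_id
            and self.text == other.text
            and self.properties == other.properties
            and list(self.properties) == list(other.properties)
            and self.entities == other.entities
            and self.relations == other.relations
        )


def nfc(text: str) -> str:
    """NFC-normalize ``text`` (the package-wide ingest convention)."""
    return unicodedata.normalize("NFC", text)


# ---------------------------------------------------------------------------
# validation


def validate_document(doc: Document) -> list[Violation]:
    """Check every model invariant; return one descriptor per violation.

    Total function: never raises, an empty list means the document is valid.
    """
    out: list[Violation] = []
    n = len(doc.text)
    if not doc.doc_id:
        out.append(Violation("document", "", "empty-doc-id", "doc_id must be non-empty"))
    for key, ent in doc.entities.items():
        if ent.key != key:
            out.append(Violation("entity", key, "key-mismatch", f"entity.key={ent.key!r}"))
        if ent.type not in ENTITY_TYPES:
            out.append(Violation("entity", key, "unknown-type", f"type={ent.type!r}"))
        if not (0 <= ent.start < ent.end <= n):
            out.append(
                Violation(
                    "entity",
                    key,
                    "offset-out-of-range",
                    f"span ({ent.start}, {ent.end}) vs text length {n}",
                )
            )
        elif doc.text[ent.start : ent.end] != ent.surface:
            out.append(
                Violation(
                    "entity",
                    key,
                    "surface-mismatch",
                    f"text slice {doc.text[ent.start:ent.end]!r} != surface {ent.surface!r}",
                )
            )
    for key, rel in doc.relations.items():
        if rel.key != key:
            out.append(Violation("relation", key, "key-mismatch", f"relation.key={rel.key!r}"))
        if not rel.arguments:
            out.append(Violation("relation", key, "empty-arguments", "relation has no arguments"))
        for role, ekey in rel.arguments.items():
            if ekey not in doc.entities:
                out.append(
                    Violation(
                        "relation",
                        key,
                        "dangling-argument",
                        f"role {role!r} references missing entity {ekey!r}",
                    )
                )
        es, ee = rel.evidence_start, rel.evidence_end
        if (es is None) != (ee is None):
            out.append(
                Violation("relation", key, "half-open-evidence", "both evidence bounds or neither")
            )
        elif es is not None and ee is not None and not (0 <= es < ee <= n):
            out.append(
                Violation(
                    "relation",
                    key,
                    "evidence-out-of-range",
                    f"evidence ({es}, {ee}) vs text length {n}",
                )
            )
    return out


def _require_valid(doc: Document) -> None:
    violations = validate_document(doc)
    if violations:
        raise DocumentValidationError(violations)


# ---------------------------------------------------------------------------
# JSON serialization


def _entity_to_json(ent: Entity) -> dict:
    return {
        "end": ent.end,
        "norm_ids": [[s, i] for s, i in ent.norm_ids],
        "start": ent.start,
        "surface": ent.surface,
        "tool": ent.tool,
        "type": ent.type,
    }


def _relation_to_json(rel: Relation) -> dict:
    obj: dict = {
        "arguments": {r: rel.arguments[r] for r in sorted(rel.arguments)},
        "tool": rel.tool,
        "type": rel.type,
    }
    if rel.evidence_start is not None:
        obj["evidence_end"] = rel.evidence_end
        obj["evidence_start"] = rel.evidence_start
    return obj


def document_to_jsonable(doc: Document) -> dict:
    """Canonical plain-dict form: sorted keys, except ``properties`` which
    keeps its insertion order."""
    return {
        "doc_id": doc.doc_id,
        "entities": {k: _entity_to_json(doc.entities[k]) for k in sorted(doc.entities)},
        "properties": dict(doc.properties),
        "relations": {k: _relation_to_json(doc.relations[k]) for k in sorted(doc.relations)},
        "text": doc.text,
    }


def write_document_json(doc: Document, stream: IO[str] | None = None) -> str:
    """Serialize ``doc`` canonically; equal documents give identical bytes.

    Raises :class:`DocumentValidationError` before writing anything if the
    document violates an invariant (no partial output).
    """
    _require_valid(doc)
    text = json.dumps(
        document_to_jsonable(doc), ensure_ascii=False, separators=(",", ":"), sort_keys=False
    )
    if stream is not None:
        stream.write(text)
    return text


def _parse_entity(key: str, obj: object) -> Entity:
    if not isinstance(obj, dict):
        raise DocumentParseError(f"entity {key!r}: expected object")
    try:
        norm_raw = obj.get("norm_ids", [])
        norm_ids = [(str(s), str(i)) for s, i in norm_raw]
        return Entity(
            key=key,
            type=str(obj["type"]),
            start=int(obj["start"]),
            end=int(obj["end"]),
            surface=str(obj["surface"]),
            tool=str(obj.get("tool", "")),
            norm_ids=norm_ids,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DocumentParseError(f"entity {key!r}: malformed field ({exc})") from exc


def _parse_relation(key: str, obj: object) -> Relation:
    if not isinstance(obj, dict):
        raise DocumentParseError(f"relation {key!r}: expected object")
    try:
        args = obj["arguments"]
        if not isinstance(args, dict):
            raise TypeError("arguments must be an object")
        es = obj.get("evidence_start")
        ee = obj.get("evidence_end")
        return Relation(
            key=key,
            type=str(obj["type"]),
            tool=str(obj.get("tool", "")),
            arguments={str(r): str(k) for r, k in args.items()},
            evidence_start=None if es is None else int(es),
            evidence_end=None if ee is None else int(ee),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise DocumentParseError(f"relation {key!r}: malformed field ({exc})") from exc


def document_from_jsonable(obj: object) -> Document:
    """Build and validate a :class:`Document` from a parsed JSON object."""
    if not isinstance(obj, dict):
        raise DocumentParseError("document: expected a JSON object")
    for fld in ("doc_id", "text"):
        if fld not in obj:
            raise DocumentParseError(f"document: missing required field {fld!r}")
    props = obj.get("properties", {})
    if not isinstance(props, dict):
        raise DocumentParseError("document: 'properties' must be an object")
    ents_raw = obj.get("entities", {})
    rels_raw = obj.get("relations", {})
    if not isinstance(ents_raw, dict) or not isinstance(rels_raw, dict):
        raise DocumentParseError("document: 'entities' and 'relations' must be objects")
    doc = Document(
        doc_id=str(obj["doc_id"]),
        text=nfc(str(obj["text"])),
        properties={str(k): str(v) for k, v in props.items()},
        entities={str(k): _parse_entity(str(k), v) for k, v in ents_raw.items()},
        relations={str(k): _parse_relation(str(k), v) for k, v in rels_raw.items()},
    )
    _require_valid(doc)
    return doc


def read_document_json(stream: Union[str, bytes, IO]) -> Document:
    """Parse one document JSON object from a string, bytes or file object."""
    if isinstance(stream, bytes):
        raw = stream.decode("utf-8")
    elif isinstance(stream, str):
        raw = stream
    else:
        raw = stream.read()
        if isinstance(raw, bytes):
            raw = raw.decode("utf-8")
    try:
        obj = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise DocumentParseError(f"malformed JSON: {exc}") from exc
    return document_from_jsonable(obj)


def write_document_collection(docs: Iterable[Document], stream: IO[str]) -> None:
    """Write documents as newline-delimited canonical JSON."""
    for doc in docs:
        stream.write(write_document_json(doc))
        stream.write("\n")


def read_document_collection(stream: Union[str, IO]) -> Iterator[Document]:
    """Read newline-delimited document JSON; yields documents lazily."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for line in stream:
        line = line.strip()
        if line:
            yield read_document_json(line)
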