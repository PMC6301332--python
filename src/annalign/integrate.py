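"""Entity normalization, multi-tool merging, relation networks and coverage stats.

After per-tool annotations have been realigned onto the original text, this
module performs the post-processing that makes results from different tools
comparable:

* :func:`normalize_entities` attaches database identifiers (NCBI gene IDs,
  disease-ontology IDs, ...) to entity mentions by offset overlap with an
  independent NER/normalization layer (PubTator-style annotations), so
  synonyms collapse to one identifier.
* :func:`apply_id_mapping` translates identifiers across databases with a
  tabular mapping (e.g. NCBI gene ID → UniProt accession).
* :func:`merge_documents` unions per-tool documents over identical text into
  one multi-tool document with provenance-namespaced keys.
* :func:`build_network` assembles an evidence-weighted relation network
  across a document collection: entities merge by normalization ID (falling
  back to the exact text mention), and each edge is weighted by the number
  of distinct extraction instances supporting it.
* :func:`corpus_stats` tabulates how many documents carry relations from
  1, 2, ... tools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Optional, Sequence, Union

import networkx as nx

from .docmodel import Document, Entity, Relation

__all__ = [
    "NerAnnotation",
    "IdMappingTable",
    "RelationNetwork",
    "ToolCoverageTable",
    "parse_pubtator",
    "normalize_entities",
    "apply_id_mapping",
    "merge_documents",
    "build_network",
    "corpus_stats",
    "corpus_stats_from_counts",
]

logger = logging.getLogger(__name__)

# Gene-like mentions share one normalization pool: NER layers tag "Gene"
# where extraction tools distinguish proteins, kinases and miRNAs.
_GENE_LIKE = frozenset({"gene", "protein", "mirna"})

#: Preferred identifier sources for node merging, most preferred first.
PREFERRED_ID_SOURCES = ("UniProt", "NCBI_gene")


@dataclass(frozen=True)
class NerAnnotation:
    """One normalized NER span over the *original* document text."""

    doc_id: str
    start: int
    end: int
    type: str
    source: str  # identifier namespace, e.g. "NCBI_gene", "MESH"
    identifier: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")
        if not self.identifier:
            raise ValueError("identifier must be non-empty")


# PubTator entity-type labels → internal types, and the identifier namespace
# conventionally used for each.
_PUBTATOR_TYPES = {
    "gene": ("gene", "NCBI_gene"),
    "species": ("other", "NCBI_taxonomy"),
    "disease": ("disease", "MESH"),
    "chemical": ("chemical", "MESH"),
    "mutation": ("mutation", "tmVar"),
    "protein": ("protein", "NCBI_gene"),
    "mirna": ("mirna", "NCBI_gene"),
}


def parse_pubtator(stream: Union[str, IO[str]]) -> list[NerAnnotation]:
    """Parse PubTator-style TSV: ``PMID<TAB>start<TAB>end<TAB>mention<TAB>type<TAB>id``.

    Identifiers already carrying a ``source:`` prefix keep it; bare
    identifiers get the namespace conventional for their entity type (NCBI
    gene IDs for genes, MeSH for diseases and chemicals).
    """
    if not isinstance(stream, str):
        stream = stream.read()
    out: list[NerAnnotation] = []
    for lineno, line in enumerate(stream.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"line {lineno}: expected 6 tab-separated fields, got {len(parts)}")
        doc_id, start, end, _mention, etype, ident = parts
        etype_l = etype.lower()
        itype, default_source = _PUBTATOR_TYPES.get(etype_l, ("other", etype_l))
        if ":" in ident:
            source, ident_val = ident.split(":", 1)
        else:
            source, ident_val = default_source, ident
        out.append(
            NerAnnotation(
                doc_id=doc_id,
                start=int(start),
                end=int(end),
                type=itype,
                source=source,
                identifier=ident_val,
            )
        )
    return out


def _types_compatible(entity_type: str, ann_type: str) -> bool:
    if entity_type in _GENE_LIKE and ann_type in _GENE_LIKE:
        return True
    return entity_type == ann_type and entity_type in {"disease", "chemical", "mutation"}


def normalize_entities(doc: Document, anns: Sequence[NerAnnotation]) -> Document:
    """Assign database identifiers to entities by offset overlap with NER spans.

    Every entity overlapping at least one type-compatible annotation gains
    the identifier of the annotation with maximal character overlap (ties
    break toward the earliest annotation start, then earliest end, then
    lexicographic identifier, so the result is independent of annotation
    order). Entities with no overlapping annotation are kept unchanged,
    without a normalization ID.
    """
    for ann in anns:
        if ann.doc_id != doc.doc_id:
            raise ValueError(
                f"annotation for document {ann.doc_id!r} applied to {doc.doc_id!r}"
            )
    out = doc.copy()
    for ent in out.entities.values():
        best: Optional[tuple] = None
        for ann in anns:
            if not _types_compatible(ent.type, ann.type):
                continue
            overlap = min(ent.end, ann.end) - max(ent.start, ann.start)
            if overlap <= 0:
                continue
            rank = (-overlap, ann.start, ann.end, ann.source, ann.identifier)
            if best is None or rank < best[0]:
                best = (rank, ann)
        if best is not None:
            ann = best[1]
            pair = (ann.source, ann.identifier)
            if pair not in ent.norm_ids:
                ent.norm_ids.append(pair)
    return out


@dataclass
class IdMappingTable:
    """Ordered (source_id → target_id) rows; duplicates allowed, first wins."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, stream: Union[str, IO[str]]) -> "IdMappingTable":
        """Read a 2-column TSV (comment lines starting with '#' are skipped)."""
        if not isinstance(stream, str):
            stream = stream.read()
        rows = []
        for line in stream.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            src, tgt = line.rstrip("\n").split("\t")[:2]
            rows.append((src, tgt))
        return cls(rows)

    def first_match(self, source_id: str) -> Optional[str]:
        for src, tgt in self.rows:
            if src == source_id:
                return tgt
        return None


def apply_id_mapping(
    doc: Document, table: IdMappingTable, source: str, target_source: str
) -> Document:
    """Append cross-database identifiers to entities via a mapping table.

    For each entity whose first ``source`` identifier appears in the table,
    the first matching target row is appended as a ``(target_source, id)``
    pair. Identifiers absent from the table are left unchanged and logged.
    """
    lookup: dict[str, str] = {}
    for src, tgt in table.rows:
        lookup.setdefault(src, tgt)  # first row wins
    out = doc.copy()
    for ent in out.entities.values():
        src_ids = [i for s, i in ent.norm_ids if s == source]
        if not src_ids:
            continue
        target = lookup.get(src_ids[0])
        if target is None:
            logger.info(
                "doc %s: entity %s id %s:%s has no %s mapping",
                doc.doc_id, ent.key, source, src_ids[0], target_source,
            )
            continue
        pair = (target_source, target)
        if pair not in ent.norm_ids:
            ent.norm_ids.append(pair)
    return out


def _entity_signature(ent: Entity) -> tuple:
    return (ent.start, ent.end, ent.type, tuple(sorted(ent.norm_ids)))


def _merge_tools(existing: str, new: str) -> str:
    tools = [t for t in existing.split(",") if t]
    for t in new.split(","):
        if t and t not in tools:
            tools.append(t)
    return ",".join(tools)


def merge_documents(per_tool_docs: Sequence[Document]) -> Document:
    """Union per-tool documents over one text into a single document.

    All inputs must share ``doc_id`` and byte-identical text (run
    realignment first). Keys are namespaced ``<tool>.<localkey>`` for
    collision-free provenance; exact duplicates across tools — same span,
    type and normalization IDs for entities, same type/arguments/evidence
    signature for relations — collapse to one record listing every
    contributing tool.
    """
    if not per_tool_docs:
        raise ValueError("merge_documents requires at least one document")
    first = per_tool_docs[0]
    for doc in per_tool_docs[1:]:
        if doc.doc_id != first.doc_id:
            raise ValueError(f"doc_id mismatch: {doc.doc_id!r} vs {first.doc_id!r}")
        if doc.text != first.text:
            raise ValueError(
                f"document texts differ for {doc.doc_id!r}; realign tool outputs "
                "to the original text before merging"
            )
    merged = Document(doc_id=first.doc_id, text=first.text, properties=dict(first.properties))
    ent_by_sig: dict[tuple, str] = {}  # signature -> merged key
    key_map: dict[tuple[int, str], str] = {}  # (doc index, local key) -> merged key
    for di, doc in enumerate(per_tool_docs):
        for key, ent in doc.entities.items():
            sig = _entity_signature(ent)
            if sig in ent_by_sig:
                kept_key = ent_by_sig[sig]
                kept = merged.entities[kept_key]
                kept.tool = _merge_tools(kept.tool, ent.tool)
                key_map[(di, key)] = kept_key
                continue
            primary_tool = ent.tool.split(",")[0] or "unknown"
            new_key = key if key.startswith(primary_tool + ".") else f"{primary_tool}.{key}"
            new_ent = ent.copy()
            new_ent.key = new_key
            merged.entities[new_key] = new_ent
            ent_by_sig[sig] = new_key
            key_map[(di, key)] = new_key
    rel_by_sig: dict[tuple, str] = {}
    for di, doc in enumerate(per_tool_docs):
        for key, rel in doc.relations.items():
            args = {role: key_map[(di, ekey)] for role, ekey in rel.arguments.items()}
            sig = (
                rel.type,
                tuple(sorted(args.items())),
                rel.evidence_start,
                rel.evidence_end,
            )
            if sig in rel_by_sig:
                kept = merged.relations[rel_by_sig[sig]]
                kept.tool = _merge_tools(kept.tool, rel.tool)
                continue
            primary_tool = rel.tool.split(",")[0] or "unknown"
            new_key = key if key.startswith(primary_tool + ".") else f"{primary_tool}.{key}"
            merged.relations[new_key] = Relation(
                key=new_key,
                type=rel.type,
                tool=rel.tool,
                arguments=args,
                evidence_start=rel.evidence_start,
                evidence_end=rel.evidence_end,
            )
            rel_by_sig[sig] = new_key
    return merged


# ---------------------------------------------------------------------------
# relation network


@dataclass
class NetworkNode:
    merge_key: str
    label: str
    type: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (doc_id, entity key)


@dataclass
class NetworkEdge:
    source: str
    target: str
    type: str
    evidence: list[tuple[str, str, str]] = field(default_factory=list)  # (doc_id, tool, rel key)

    @property
    def weight(self) -> int:
        return len(self.evidence)


@dataclass
class RelationNetwork:
    """Merged entity nodes and evidence-weighted relation edges.

    Nodes are keyed by preferred normalization ID (UniProt before NCBI gene
    before any other source) or, when no ID is available, by the
    whitespace-normalized text mention. One undirected edge exists per
    (node pair, relation type); its weight is the number of distinct
    ``(doc_id, tool, relation key)`` evidence items.
    """

    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], NetworkEdge] = field(default_factory=dict)

    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges.values())

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for key, node in self.nodes.items():
            g.add_node(key, label=node.label, type=node.type)
        for (u, v, rtype), edge in self.edges.items():
            g.add_edge(
                u,
                v,
                key=rtype,
                type=rtype,
                weight=edge.weight,
                evidence=json.dumps(sorted(edge.evidence)),
            )
        return g

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_jsonable(self) -> dict:
        return {
            "nodes": [
                {
                    "id": k,
                    "label": n.label,
                    "type": n.type,
                    "members": [list(m) for m in sorted(n.members)],
                }
                for k, n in sorted(self.nodes.items())
            ],
            "edges": [
                {
                    "source": u,
                    "target": v,
                    "type": t,
                    "weight": e.weight,
                    "evidence": [list(i) for i in sorted(e.evidence)],
                }
                for (u, v, t), e in sorted(self.edges.items())
            ],
        }


def _normalize_mention(surface: str) -> str:
    return " ".join(surface.split())


def node_merge_key(ent: Entity) -> str:
    """Merge key for an entity: preferred DB identifier, else exact mention."""
    for source in PREFERRED_ID_SOURCES:
        for s, i in ent.norm_ids:
            if s == source:
                return f"{s}:{i}"
    if ent.norm_ids:
        s, i = ent.norm_ids[0]
        return f"{s}:{i}"
    return f"mention:{_normalize_mention(ent.surface)}"


def build_network(docs: Iterable[Document]) -> RelationNetwork:
    """Build the evidence-weighted relation network over a document collection.

    Entities normalized to the same identifier merge into one node; entities
    without an identifier merge by identical (whitespace-normalized,
    case-sensitive) text mention. Each relation contributes one evidence
    item ``(doc_id, tool, relation key)`` to the edge between its first two
    distinct argument nodes in role-name order (a self-loop when all
    arguments merge), so the total edge weight equals the number of
    deduplicated evidence items. Insensitive to document order.
    """
    net = RelationNetwork()
    seen_evidence: set[tuple[str, str, str]] = set()
    for doc in sorted(docs, key=lambda d: d.doc_id):
        keys = {ekey: node_merge_key(ent) for ekey, ent in doc.entities.items()}
        for ekey in sorted(doc.entities):
            ent = doc.entities[ekey]
            mkey = keys[ekey]
            node = net.nodes.get(mkey)
            if node is None:
                node = NetworkNode(
                    merge_key=mkey, label=_normalize_mention(ent.surface), type=ent.type
                )
                net.nodes[mkey] = node
            node.members.append((doc.doc_id, ekey))
        for rkey in sorted(doc.relations):
            rel = doc.relations[rkey]
            item = (doc.doc_id, rel.tool, rkey)
            if item in seen_evidence:
                continue
            seen_evidence.add(item)
            arg_nodes = [keys[rel.arguments[role]] for role in sorted(rel.arguments)]
            endpoints = [arg_nodes[0]]
            for nk in arg_nodes[1:]:
                if nk != endpoints[0]:
                    endpoints.append(nk)
                    break
            u = endpoints[0]
            v = endpoints[1] if len(endpoints) > 1 else u
            u, v = (u, v) if u <= v else (v, u)
            ekey_t = (u, v, rel.type)
            edge = net.edges.get(ekey_t)
            if edge is None:
                edge = NetworkEdge(source=u, target=v, type=rel.type)
                net.edges[ekey_t] = edge
            edge.evidence.append(item)
    return net


# ---------------------------------------------------------------------------
# coverage statistics


def _pct(count: int, total: int) -> Decimal:
    return (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )


@dataclass
class ToolCoverageTable:
    """Documents broken down by how many distinct tools found a relation.

    ``rows`` maps number-of-tools (1..T) to ``(count, percentage)`` with
    percentages computed as 100·count/total rounded half-up to 2 decimals.
    """

    rows: dict[int, tuple[int, Decimal]]
    total: int

    def percentages(self) -> list[Decimal]:
        return [self.rows[k][1] for k in sorted(self.rows)]

    def counts(self) -> list[int]:
        return [self.rows[k][0] for k in sorted(self.rows)]


def corpus_stats_from_counts(counts: Sequence[int]) -> ToolCoverageTable:
    """Build the coverage table from pre-tabulated per-tool-count tallies.

    ``counts[i]`` is the number of documents with relations from exactly
    ``i + 1`` distinct tools.
    """
    total = sum(counts)
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    rows = {i + 1: (c, _pct(c, total)) for i, c in enumerate(counts)}
    return ToolCoverageTable(rows=rows, total=total)


def corpus_stats(docs: Iterable[Document]) -> ToolCoverageTable:
    """Count documents by the number of distinct tools contributing relations.

    Documents without any relation are excluded from the tally (the table
    describes documents *with* extracted relations). Raises on an empty
    collection.
    """
    tallies: dict[int, int] = {}
    n_docs = 0
    for doc in docs:
        n_docs += 1
        tools: set[str] = set()
        for rel in doc.relations.values():
            tools.update(t for t in rel.tool.split(",") if t)
        if tools:
            tallies[len(tools)] = tallies.get(len(tools), 0) + 1
    if n_docs == 0:
        raise ValueError("empty document collection")
    if not tallies:
        raise ValueError("no document carries any relation")
    counts = [tallies.get(k, 0) for k in range(1, max(tallies) + 1)]
    return corpus_stats_from_counts(counts)
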