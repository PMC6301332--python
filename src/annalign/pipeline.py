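"""Chunked batch execution of external tool adapters.

Large corpora are processed in small contiguous chunks (100 documents by
default) so that per-task memory stays bounded and failed work is isolated:
an adapter that crashes on one chunk quarantines only that chunk, recorded
in a failures file, while the rest of the batch completes. Chunks are
independent and share no mutable state, so results do not depend on the
order or degree of parallel execution.

An *adapter* is any external command that reads newline-delimited document
JSON on standard input and writes the same on standard output — the
containerized-tool contract reduced to a plain subprocess.
"""

from __future__ import annotations

import io
import json
import logging
import subprocess
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .docmodel import (
    Document,
    DocumentParseError,
    DocumentValidationError,
    read_document_collection,
    write_document_collection,
)

__all__ = ["ChunkPlan", "ChunkFailure", "BatchResult", "chunk_corpus", "run_adapter"]

logger = logging.getLogger(__name__)

DEFAULT_CHUNK_SIZE = 100


@dataclass
class ChunkPlan:
    """Deterministic contiguous partition of a corpus into fixed-size chunks.

    All chunks except possibly the last contain exactly ``chunk_size``
    document ids; concatenating the chunks in index order restores the
    input order.
    """

    chunk_size: int
    chunks: list[list[str]]

    def __len__(self) -> int:
        return len(self.chunks)


def chunk_corpus(doc_ids: Sequence[str], chunk_size: int = DEFAULT_CHUNK_SIZE) -> ChunkPlan:
    """Partition ``doc_ids`` into contiguous chunks of ``chunk_size``."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    ids = list(doc_ids)
    if not ids:
        raise ValueError("cannot chunk an empty corpus")
    chunks = [ids[i : i + chunk_size] for i in range(0, len(ids), chunk_size)]
    return ChunkPlan(chunk_size=chunk_size, chunks=chunks)


@dataclass
class ChunkFailure:
    chunk_index: int
    doc_ids: list[str]
    reason: str


@dataclass
class BatchResult:
    documents: list[Document] = field(default_factory=list)
    failures: list[ChunkFailure] = field(default_factory=list)

    def write_failures(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in self.failures:
                fh.write(
                    json.dumps(
                        {"chunk_index": f.chunk_index, "doc_ids": f.doc_ids, "reason": f.reason}
                    )
                    + "\n"
                )


def _run_one_chunk(docs: Sequence[Document], command: Sequence[str], timeout: Optional[float]) -> list[Document]:
    buf = io.StringIO()
    write_document_collection(docs, buf)
    proc = subprocess.run(
        list(command),
        input=buf.getvalue(),
        capture_output=True,
        text=True,
        timeout=timeout,
    )
    if proc.returncode != 0:
        raise RuntimeError(
            f"adapter exited with status {proc.returncode}: {proc.stderr.strip()[:500]}"
        )
    return list(read_document_collection(proc.stdout))


def run_adapter(
    docs: Sequence[Document],
    command: Sequence[str],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    timeout: Optional[float] = None,
) -> BatchResult:
    """Run an external adapter over a corpus, chunk by chunk.

    The adapter command is launched once per chunk with newline-delimited
    document JSON on stdin and must emit the same on stdout. A nonzero exit
    status or unparseable output quarantines the chunk — its ids and the
    diagnostic are recorded on the result — without aborting the batch.
    """
    by_id = {d.doc_id: d for d in docs}
    plan = chunk_corpus([d.doc_id for d in docs], chunk_size)
    result = BatchResult()
    for index, ids in enumerate(plan.chunks):
        chunk_docs = [by_id[i] for i in ids]
        try:
            result.documents.extend(_run_one_chunk(chunk_docs, command, timeout))
        except (RuntimeError, DocumentParseError, DocumentValidationError,
                subprocess.TimeoutExpired, OSError) as exc:
            logger.warning("chunk %d quarantined: %s", index, exc)
            result.failures.append(ChunkFailure(index, list(ids), str(exc)))
    return result
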