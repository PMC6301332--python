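import pytest

from annalign.docmodel import Document, Entity, Relation
from annalign.synthcorpus import PERTURBATION_KINDS, PerturbationSpec, generate_corpus


@pytest.fixture
def annotated_doc() -> Document:
    """One document with one entity pair and one relation (the canonical
    record shape: doc id, text, properties, entity and relation hash tables)."""
    text = "AKT1 phosphorylates PTEN at Ser380."
    doc = Document(
        doc_id="12345",
        text=text,
        properties={"section_type": "abstract", "paragraph_index": "0"},
    )
    doc.entities["E1"] = Entity(
        key="E1", type="protein", start=0, end=4, surface="AKT1", tool="rlimsp",
        norm_ids=[("NCBI_gene", "207"), ("UniProt", "P31749")],
    )
    doc.entities["E2"] = Entity(
        key="E2", type="protein", start=20, end=24, surface="PTEN", tool="rlimsp",
        norm_ids=[("NCBI_gene", "5728")],
    )
    doc.entities["E3"] = Entity(
        key="E3", type="other", start=28, end=34, surface="Ser380", tool="rlimsp",
    )
    doc.relations["R1"] = Relation(
        key="R1", type="phosphorylation", tool="rlimsp",
        arguments={"kinase": "E1", "substrate": "E2", "site": "E3"},
        evidence_start=0, evidence_end=35,
    )
    return doc


@pytest.fixture(scope="session")
def default_specs() -> list[PerturbationSpec]:
    """Every perturbation kind at rate 0.3 (the default study conditions)."""
    return [
        PerturbationSpec(kind=k, rate=0.3, seed=100 + i)
        for i, k in enumerate(PERTURBATION_KINDS)
    ]


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(25, 42)
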