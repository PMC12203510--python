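import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from synfuse.records import DrugRecord, EmbeddingTable, SynergyRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_records():
    return [
        SynergyRecord("A", "B", "c1", {"loewe": 1.0}),
        SynergyRecord("A", "B", "c1", {"loewe": 3.0}),
        SynergyRecord("B", "A", "c2", {"loewe": 4.0}),
        SynergyRecord("A", "B", "c2", {"loewe": 2.0}),
        SynergyRecord("A", "C", "c1", {"loewe": 5.0}),
    ]


@pytest.fixture
def small_embeddings(rng):
    return EmbeddingTable({f"P{i}": rng.standard_normal(6) for i in range(10)})


@pytest.fixture
def drug_ab():
    return (
        DrugRecord("A", smiles="CC(=O)OC1=CC=CC=C1C(=O)O",
                   target_ids={"P0", "P1"}, pathway_ids={"PW0"}),
        DrugRecord("B", smiles="CN1C=NC2=C1C(=O)N(C)C(=O)N2C",
                   target_ids={"P2"}, pathway_ids={"PW0", "PW1"}),
    )
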