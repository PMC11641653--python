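import numpy as np
import pytest

from mirlink import (
    AssociationTable,
    EmbeddingTable,
    SequenceKind,
    SequenceRecord,
    Alphabet,
)


@pytest.fixture
def toy_records():
    mirnas = [
        SequenceRecord("mir-a", SequenceKind.MIRNA, "ACGTACGTACGTACGTAC", Alphabet.RNA),
        SequenceRecord("mir-b", SequenceKind.MIRNA, "TTGCATGCATGCATGCAT", Alphabet.RNA),
        SequenceRecord("mir-c", SequenceKind.MIRNA, "GGGTTTCCCAAAGGGTTT", Alphabet.RNA),
    ]
    genes = [
        SequenceRecord("g1", SequenceKind.GENE, "ACGT" * 20, Alphabet.DNA),
        SequenceRecord("g2", SequenceKind.GENE, "TTGC" * 20, Alphabet.DNA),
        SequenceRecord("g3", SequenceKind.GENE, "GGCA" * 20, Alphabet.DNA),
    ]
    return mirnas, genes


@pytest.fixture
def toy_table(toy_records):
    """Hand-set 4-d embeddings for the 3 miRNAs and 3 genes."""
    rng = np.random.default_rng(42)
    mirnas, genes = toy_records
    vectors = {
        r.id: rng.normal(size=4) for r in mirnas + genes
    }
    return EmbeddingTable(4, vectors)


@pytest.fixture
def toy_positives():
    return AssociationTable([("mir-a", "g1", 1), ("mir-b", "g2", 1), ("mir-c", "g3", 1)])
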