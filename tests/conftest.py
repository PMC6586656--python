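import numpy as np
import pytest

from hsp70typer import SeqRecord
from hsp70typer.motif_typing import AMINO_ACIDS, ReferenceModel
from hsp70typer.synthetic_fixtures import gen_protein

# one codon per amino acid, for deterministic reverse translation in tests
CODON_FOR = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(aa: str, stop: str = "TAA") -> str:
    """A complete ORF nucleotide sequence encoding ``aa``."""
    return "".join(CODON_FOR[c] for c in aa) + stop


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def reference() -> ReferenceModel:
    """A synthetic 641-residue heat-inducible reference protein."""
    rec, _ = gen_protein("protein_inducible", seed=0)
    return ReferenceModel(accession="SYNREF_INDUCIBLE", aa_sequence=rec.sequence)


@pytest.fixture()
def protein_record():
    def make(seq: str, rid: str = "q") -> SeqRecord:
        return SeqRecord(id=rid, sequence=seq, moltype="protein")

    return make


@pytest.fixture()
def dna_record():
    def make(seq: str, rid: str = "d") -> SeqRecord:
        return SeqRecord(id=rid, sequence=seq, moltype="dna")

    return make
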