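import numpy as np
import pytest

from seqevolve import build_alphabet, FrequencyVector


@pytest.fixture(scope="session")
def codon_alphabet():
    return build_alphabet("codon")


@pytest.fixture(scope="session")
def nuc_alphabet():
    return build_alphabet("nucleotide")


@pytest.fixture(scope="session")
def aa_alphabet():
    return build_alphabet("amino_acid")


@pytest.fixture
def uniform_codon_freqs(codon_alphabet):
    return FrequencyVector.uniform(codon_alphabet)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_fasta(tmp_path):
    """Two-sequence nucleotide alignment 'AC' / 'AG'."""
    p = tmp_path / "aln.fasta"
    p.write_text(">s1\nAC\n>s2\nAG\n")
    return str(p)
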