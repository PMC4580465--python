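"""State alphabets and the genetic code.

Every model in the package operates on an ordered state alphabet: the four
DNA nucleotides, the twenty amino acids, the 61 sense codons of the standard
genetic code, or an arbitrary user-defined state set (e.g. morphological
characters "0", "1", "2" for an Mk-style model).  Orderings are fixed
(A,C,G,T; alphabetical one-letter amino acids; alphabetical codons) so that
rate matrices and frequency vectors are bit-comparable across runs.

Only DNA symbols are used internally; RNA input ('U') is normalized to 'T'
by the readers in :mod:`seqevolve.frequencies`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

from Bio.Data import CodonTable

NUCLEOTIDES = ("A", "C", "G", "T")
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)  # TAA, TAG, TGA
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)

PURINES = frozenset({"A", "G"})


def is_transition(x: str, y: str) -> bool:
    """True if x<->y is a transition (A<->G or C<->T)."""
    return x != y and (x in PURINES) == (y in PURINES)


class AlphabetError(ValueError):
    """Invalid alphabet construction or state lookup."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> one-letter amino acid translation table.

    Only the standard code is bundled, but the table is plain data so
    alternative codes can be supplied.
    """

    table: dict[str, str]
    stop_codons: frozenset[str]

    def translate(self, codon: str) -> str:
        try:
            return self.table[codon]
        except KeyError:
            raise AlphabetError(f"cannot translate {codon!r}: not a sense codon") from None

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def synonymous_codons(self, aa: str) -> tuple[str, ...]:
        return tuple(c for c, a in self.table.items() if a == aa)


STANDARD_CODE = GeneticCode(
    table={c: _STANDARD.forward_table[c] for c in SENSE_CODONS},
    stop_codons=STOP_CODONS,
)


class AlphabetKind(str, Enum):
    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"
    CODON = "codon"
    CUSTOM = "custom"


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of distinct state tokens with index lookup."""

    kind: AlphabetKind
    states: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.states)})

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, state: str) -> bool:
        return state in self._index

    def index_of(self, state: str) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise AlphabetError(f"state {state!r} not in {self.kind.value} alphabet") from None

    @property
    def state_width(self) -> int:
        """Characters per state (3 for codons, else token length)."""
        return len(self.states[0])


def build_alphabet(kind: str | AlphabetKind, custom_states: list[str] | None = None) -> Alphabet:
    """Build a canonical alphabet.

    Parameters
    ----------
    kind
        One of ``nucleotide``, ``amino_acid``, ``codon``, ``custom``.
    custom_states
        Required iff ``kind == "custom"``; at least two distinct non-empty
        tokens, kept in the given order.
    """
    kind = AlphabetKind(kind)
    if kind is AlphabetKind.CUSTOM:
        if not custom_states:
            raise AlphabetError("custom alphabet requires custom_states")
        seen: set[str] = set()
        for tok in custom_states:
            if not isinstance(tok, str) or tok == "":
                raise AlphabetError(f"empty or non-string custom state: {tok!r}")
            if tok in seen:
                raise AlphabetError(f"duplicate custom state: {tok!r}")
            seen.add(tok)
        if len(custom_states) < 2:
            raise AlphabetError("custom alphabet needs at least 2 states")
        return Alphabet(kind, tuple(custom_states))
    if custom_states is not None:
        raise AlphabetError(f"custom_states only valid with kind='custom', not {kind.value!r}")
    if kind is AlphabetKind.NUCLEOTIDE:
        return Alphabet(kind, NUCLEOTIDES)
    if kind is AlphabetKind.AMINO_ACID:
        return Alphabet(kind, AMINO_ACIDS)
    return Alphabet(kind, SENSE_CODONS)


class CodonPairClass(str, Enum):
    IDENTICAL = "identical"
    SYNONYMOUS_SINGLE = "synonymous_single"
    NONSYNONYMOUS_SINGLE = "nonsynonymous_single"
    MULTI_NUCLEOTIDE = "multi_nucleotide"


def codon_diff_positions(c1: str, c2: str) -> list[int]:
    return [i for i in range(3) if c1[i] != c2[i]]


def classify_codon_pair(c1: str, c2: str, code: GeneticCode = STANDARD_CODE) -> CodonPairClass:
    """Classify an ordered codon pair by number of differing positions and,
    for single-nucleotide differences, whether translation is preserved."""
    for c in (c1, c2):
        if code.is_stop(c):
            raise AlphabetError(f"stop codon {c!r} not allowed")
        if c not in code.table:
            raise AlphabetError(f"{c!r} is not a sense codon")
    ndiff = len(codon_diff_positions(c1, c2))
    if ndiff == 0:
        return CodonPairClass.IDENTICAL
    if ndiff > 1:
        return CodonPairClass.MULTI_NUCLEOTIDE
    if code.translate(c1) == code.translate(c2):
        return CodonPairClass.SYNONYMOUS_SINGLE
    return CodonPairClass.NONSYNONYMOUS_SINGLE
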