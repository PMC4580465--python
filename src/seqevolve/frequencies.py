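"""State-frequency vectors: empirical, random, constrained, and converted.

A :class:`FrequencyVector` holds per-state probabilities over an
:class:`~seqevolve.alphabets.Alphabet`.  Frequencies can be counted from
FASTA/PHYLIP files (globally or from selected alignment columns), drawn
uniformly on the simplex, constrained to a subset of states, or converted
between the codon, amino-acid, and nucleotide alphabets via the genetic
code (e.g. simulate amino-acid data with frequencies read from codon data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

from .alphabets import (
    Alphabet,
    AlphabetKind,
    GeneticCode,
    STANDARD_CODE,
    build_alphabet,
)

_SKIP_CHARS = {"-", "?", "."}
_AMBIGUOUS = {
    AlphabetKind.NUCLEOTIDE: {"N"},
    AlphabetKind.AMINO_ACID: {"X"},
    AlphabetKind.CODON: set(),  # handled per-nucleotide
    AlphabetKind.CUSTOM: set(),
}


class FrequencyError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyVector:
    alphabet: Alphabet
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.alphabet),):
            raise FrequencyError(
                f"expected {len(self.alphabet)} frequencies, got {v.shape}"
            )
        if np.any(v < 0):
            raise FrequencyError("negative frequency")
        if abs(v.sum() - 1.0) > 1e-10:
            raise FrequencyError(f"frequencies sum to {v.sum()!r}, not 1")

    def __getitem__(self, state: str) -> float:
        return float(self.values[self.alphabet.index_of(state)])

    @classmethod
    def uniform(cls, alphabet: Alphabet) -> "FrequencyVector":
        n = len(alphabet)
        return cls(alphabet, np.full(n, 1.0 / n))

    @classmethod
    def from_dict(cls, alphabet: Alphabet, d: dict[str, float]) -> "FrequencyVector":
        v = np.zeros(len(alphabet))
        for state, p in d.items():
            v[alphabet.index_of(state)] = p
        return cls(alphabet, v / v.sum())


def _read_sequences(path: str, format: str) -> list[str]:
    fmt = format.lower()
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise FrequencyError(f"no sequences found in {path}")
        return [str(r.seq).upper().replace("U", "T") for r in records]
    if fmt == "phylip":
        try:
            aln = AlignIO.read(path, "phylip-relaxed")
        except ValueError:
            aln = AlignIO.read(path, "phylip")
        return [str(r.seq).upper().replace("U", "T") for r in aln]
    raise FrequencyError(f"unsupported format {format!r} (use fasta or phylip)")


def frequencies_from_file(
    path: str,
    format: str,
    target_alphabet: Alphabet,
    columns: list[int] | None = None,
    pseudocount: float = 0.0,
) -> FrequencyVector:
    """Empirical state frequencies counted from a sequence/alignment file.

    ``columns`` are 1-based alignment column indices; for a codon target they
    address codon columns (column c covers nucleotide positions 3c-2..3c).
    Gaps and fully ambiguous characters are skipped.  States never observed
    get frequency 0 unless ``pseudocount`` > 0.
    """
    seqs = _read_sequences(path, format)
    width = target_alphabet.state_width
    counts = np.full(len(target_alphabet), float(pseudocount))
    ambiguous = _AMBIGUOUS[target_alphabet.kind]
    n_counted = 0
    for si, seq in enumerate(seqs):
        if len(seq) % width:
            raise FrequencyError(
                f"sequence {si + 1} length {len(seq)} not a multiple of state width {width}"
            )
        ncol = len(seq) // width
        if columns is not None:
            for c in columns:
                if not 1 <= c <= ncol:
                    raise FrequencyError(
                        f"column {c} out of range 1..{ncol} for sequence {si + 1}"
                    )
            idx = [c - 1 for c in columns]
        else:
            idx = range(ncol)
        for col in idx:
            token = seq[col * width : (col + 1) * width]
            if any(ch in _SKIP_CHARS for ch in token):
                continue
            if target_alphabet.kind is AlphabetKind.CODON:
                if "N" in token:
                    continue
                if token in STANDARD_CODE.stop_codons:
                    continue
            elif token in ambiguous:
                continue
            if token not in target_alphabet:
                raise FrequencyError(
                    f"character {token!r} at sequence {si + 1}, column {col + 1} "
                    f"not in {target_alphabet.kind.value} alphabet"
                )
            counts[target_alphabet.index_of(token)] += 1
            n_counted += 1
    if n_counted == 0 and pseudocount == 0:
        raise FrequencyError("no countable characters in the selected columns")
    return FrequencyVector(target_alphabet, counts / counts.sum())


def random_frequencies(alphabet: Alphabet, seed: int | np.random.Generator) -> FrequencyVector:
    """Uniform point on the simplex (symmetric Dirichlet(1)); seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return FrequencyVector(alphabet, rng.dirichlet(np.ones(len(alphabet))))


def constrained_frequencies(
    alphabet: Alphabet,
    allowed_states: list[str],
    seed: int | np.random.Generator | None = None,
    explicit_values: list[float] | None = None,
) -> FrequencyVector:
    """Frequencies supported only on ``allowed_states``.

    Inside the allowed set, either the explicit values (must sum to 1) or a
    random simplex point (requires ``seed``).
    """
    if not allowed_states:
        raise FrequencyError("allowed_states is empty")
    idx = [alphabet.index_of(s) for s in allowed_states]
    v = np.zeros(len(alphabet))
    if explicit_values is not None:
        ev = np.asarray(explicit_values, dtype=float)
        if ev.shape != (len(allowed_states),):
            raise FrequencyError("explicit_values length mismatch with allowed_states")
        if abs(ev.sum() - 1.0) > 1e-8:
            raise FrequencyError(f"explicit values sum to {ev.sum()!r}, not 1")
        v[idx] = ev
    else:
        if seed is None:
            raise FrequencyError("need a seed (or explicit_values)")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        v[idx] = rng.dirichlet(np.ones(len(idx)))
    return FrequencyVector(alphabet, v / v.sum())


def convert_frequencies(
    fv: FrequencyVector,
    to_alphabet: Alphabet | str,
    code: GeneticCode = STANDARD_CODE,
) -> FrequencyVector:
    """Convert between alphabets via the genetic code.

    codon -> amino_acid: sum synonymous-codon frequencies.
    codon -> nucleotide: average the position-specific nucleotide
    frequencies implied by the codon vector over the three positions.
    amino_acid -> codon: split each amino acid's mass equally among its
    synonymous codons.
    """
    if isinstance(to_alphabet, (str, AlphabetKind)):
        to_alphabet = build_alphabet(to_alphabet)
    src, dst = fv.alphabet.kind, to_alphabet.kind
    if src is AlphabetKind.CODON and dst is AlphabetKind.AMINO_ACID:
        out = np.zeros(len(to_alphabet))
        for i, codon in enumerate(fv.alphabet.states):
            out[to_alphabet.index_of(code.translate(codon))] += fv.values[i]
    elif src is AlphabetKind.CODON and dst is AlphabetKind.NUCLEOTIDE:
        out = np.zeros(len(to_alphabet))
        for i, codon in enumerate(fv.alphabet.states):
            for pos in range(3):
                out[to_alphabet.index_of(codon[pos])] += fv.values[i] / 3.0
    elif src is AlphabetKind.AMINO_ACID and dst is AlphabetKind.CODON:
        out = np.zeros(len(to_alphabet))
        for i, aa in enumerate(fv.alphabet.states):
            syn = code.synonymous_codons(aa)
            for codon in syn:
                out[to_alphabet.index_of(codon)] += fv.values[i] / len(syn)
    else:
        raise FrequencyError(
            f"unsupported conversion {src.value} -> {dst.value}"
        )
    return FrequencyVector(to_alphabet, out / out.sum())
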