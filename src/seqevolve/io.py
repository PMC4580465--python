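"""Alignment output (FASTA, sequential PHYLIP, NEXUS) and the per-site
category sidecar file."""

from __future__ import annotations

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import AlphabetKind
from .evolve import EvolveError, SimulatedAlignment

DEFAULT_OUTPUT = "simulated_alignment.fasta"


def load_simulated_alignment(path: str, tree, format: str = "fasta"):
    """Rebuild a :class:`SimulatedAlignment` from a written alignment that
    includes ancestral records, so counting can run on files.

    Sequence ids must match the tree's tip names and the simulator's
    internal-node naming ('root', 'internal_1', ... or explicit labels).
    Sequences are interpreted as codons (the counting toolkit's use case).
    """
    import numpy as np
    from Bio import SeqIO

    from .alphabets import build_alphabet
    from .evolve import PartitionResult, _assign_node_names, _split_states
    from .partitions import Partition

    alphabet = build_alphabet("codon")
    seqs = {r.id: str(r.seq).upper().replace("U", "T") for r in SeqIO.parse(path, format)}
    if not seqs:
        raise EvolveError(f"no sequences found in {path}")
    sizes = {len(s) for s in seqs.values()}
    if len(sizes) != 1:
        raise EvolveError("sequences have unequal lengths")
    size = sizes.pop() // 3
    node_names = _assign_node_names(tree)
    states = {}
    for name in node_names.values():
        if name not in seqs:
            raise EvolveError(
                f"node {name!r} has no sequence in {path}; counting needs "
                "tip and ancestral records"
            )
        tokens = _split_states(seqs[name], alphabet)
        states[name] = [np.array([alphabet.index_of(t) for t in tokens], dtype=np.int64)]
    part = Partition(size=size, model="loaded")
    pr = PartitionResult(part, alphabet, np.zeros(size, dtype=np.int64),
                         ["loaded"] * size, np.ones(size))
    tips = [node_names[id(t)] for t in tree.tips()]
    ancestors = [node_names[id(n)] for n in tree.preorder() if not n.is_leaf]
    return SimulatedAlignment(tree, [pr], states, tips, ancestors, node_names)

_FORMATS = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


def _molecule_type(aln: SimulatedAlignment) -> str:
    kinds = {pr.alphabet.kind for pr in aln.partitions}
    if kinds <= {AlphabetKind.NUCLEOTIDE, AlphabetKind.CODON}:
        return "DNA"
    if kinds == {AlphabetKind.AMINO_ACID}:
        return "protein"
    return "DNA"  # custom states: best-effort label for writers that need one


def write_alignment(
    aln: SimulatedAlignment,
    path: str = DEFAULT_OUTPUT,
    format: str = "fasta",
    include_ancestors: bool = False,
) -> str:
    """Write tip (and optionally ancestral) sequences; codon states appear
    as nucleotide triplets.  Returns the path written."""
    try:
        biofmt = _FORMATS[format.lower()]
    except KeyError:
        raise EvolveError(
            f"unknown format {format!r}; choose from {sorted(_FORMATS)}"
        ) from None
    names = list(aln.tip_names)
    if include_ancestors:
        if not aln.ancestor_names:
            raise EvolveError("no ancestral sequences were retained in this simulation")
        names += list(aln.ancestor_names)
    mol = _molecule_type(aln)
    records = [
        SeqRecord(Seq(aln.sequence(n)), id=n, description="",
                  annotations={"molecule_type": mol})
        for n in names
    ]
    msa = MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, biofmt)
    return path


def write_site_categories(aln: SimulatedAlignment, path: str) -> str:
    """Tab-separated sidecar recording each site's partition, category,
    model, and rate factor."""
    with open(path, "w") as fh:
        fh.write("site\tpartition\tcategory\tmodel\trate\n")
        for row in aln.site_table():
            fh.write(
                f"{row['site']}\t{row['partition']}\t{row['category']}\t"
                f"{row['model']}\t{row['rate']:g}\n"
            )
    return path
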