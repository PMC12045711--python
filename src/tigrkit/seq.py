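"""Nucleotide sequence primitives shared across the toolkit.

Coordinates are 0-based half-open everywhere in this package; 1-based closed
coordinates appear only in GFF3 output.
"""

from __future__ import annotations

from dataclasses import dataclass

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")

_DNA_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_RNA_COMPLEMENT = str.maketrans("ACGURYSWKMBDHVN", "UGCAYRSWMKVHDBN")

#: Watson-Crick partner of each DNA base; doubles as the transversion map
#: used throughout (A<->T, G<->C keeps purine/pyrimidine identity swapped).
WC_DNA = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: DNA base paired by each RNA base under strict Watson-Crick rules.
WC_RNA_DNA = {"A": "T", "C": "G", "G": "C", "U": "A"}


class AlphabetError(ValueError):
    """Raised when a sequence does not conform to its declared alphabet."""


@dataclass
class NucSeq:
    """A named nucleotide sequence with an explicit DNA/RNA flag.

    Input is normalized to uppercase.  Strict bases must match ``kind``;
    IUPAC ambiguity codes are tolerated (they may occur in background
    genomic sequence) but are rejected by grammar-level operations that
    require unambiguous repeats and spacers.
    """

    id: str
    seq: str
    kind: str = "dna"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.kind not in ("dna", "rna"):
            raise ValueError(f"kind must be 'dna' or 'rna', got {self.kind!r}")
        if not self.seq:
            raise AlphabetError(f"{self.id}: empty sequence rejected")
        strict = DNA_BASES if self.kind == "dna" else RNA_BASES
        bad = set(self.seq) - strict - AMBIGUITY_CODES
        if bad:
            raise AlphabetError(
                f"{self.id}: characters {sorted(bad)} not allowed in {self.kind}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def complement(seq: str, kind: str = "dna") -> str:
    table = _DNA_COMPLEMENT if kind == "dna" else _RNA_COMPLEMENT
    return seq.translate(table)


def revcomp_str(seq: str, kind: str = "dna") -> str:
    """Reverse complement of a raw sequence string."""
    return complement(seq, kind)[::-1]


def revcomp(seq: NucSeq) -> NucSeq:
    """Reverse complement a :class:`NucSeq` (involution)."""
    return NucSeq(seq.id, revcomp_str(seq.seq, seq.kind), seq.kind)


def to_rna(seq: NucSeq) -> NucSeq:
    """Transliterate DNA to RNA (T -> U)."""
    if seq.kind == "rna":
        return NucSeq(seq.id, seq.seq, "rna")
    return NucSeq(seq.id, seq.seq.replace("T", "U"), "rna")


def to_dna(seq: NucSeq) -> NucSeq:
    """Transliterate RNA to DNA (U -> T)."""
    if seq.kind == "dna":
        return NucSeq(seq.id, seq.seq, "dna")
    return NucSeq(seq.id, seq.seq.replace("U", "T"), "dna")


def rna_to_dna_str(seq: str) -> str:
    return seq.replace("U", "T")


def dna_to_rna_str(seq: str) -> str:
    return seq.replace("T", "U")


def transversion(base: str) -> str:
    """Transversion partner of a DNA base (T->A, G->C and vice versa).

    Identical to the complement map, which guarantees the substituted base
    can no longer Watson-Crick pair with the guide base it faced.
    """
    return WC_DNA[base]


def pairs_rna_dna(rna_base: str, dna_base: str, wobble: bool = False) -> bool:
    """Whether an RNA base pairs a DNA base in an antiparallel duplex.

    Strict Watson-Crick by default; ``wobble`` additionally allows
    rG:dT and rU:dG pairs.
    """
    if WC_RNA_DNA.get(rna_base) == dna_base:
        return True
    if wobble and ((rna_base == "G" and dna_base == "T") or (rna_base == "U" and dna_base == "G")):
        return True
    return False


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def has_ambiguity(seq: str) -> bool:
    return any(c in AMBIGUITY_CODES for c in seq)
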