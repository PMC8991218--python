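"""Tiny nucleotide-sequence helpers shared across stages.

All inter-stage comparison happens in RNA space (U-normalized); genomic and
ncRNA references are stored as DNA and converted at the boundary.
"""

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")

_TO_RNA = str.maketrans("Tt", "Uu")
_TO_DNA = str.maketrans("Uu", "Tt")


def to_rna(seq: str) -> str:
    """T -> U (uppercased)."""
    return seq.upper().translate(_TO_RNA)


def to_dna(seq: str) -> str:
    """U -> T (uppercased)."""
    return seq.upper().translate(_TO_DNA)


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
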