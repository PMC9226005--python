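"""Nucleotide-string helpers shared across modules.

Sequences are handled internally in DNA letters: RNA input is normalized
with U->T on ingestion, and FASTA/FASTQ emission uses DNA letters as well.
"""

from __future__ import annotations

from .errors import EncodingError

DNA_ALPHABET = "ACGT"
_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize(seq: str, *, context: str = "sequence") -> str:
    """Upper-case, map U->T and validate against the {A,C,G,T,N} alphabet."""
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in _VALID:
            raise EncodingError(
                f"invalid character {ch!r} at position {i} in {context}"
            )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (DNA letters, N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seed_region(mirna_seq: str) -> str:
    """The seed, miRNA positions 2-7 (0-based slice [1:7])."""
    return mirna_seq[1:7]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
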