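"""Small nucleotide-string helpers shared across modules.

All internal sequence handling is uppercase RNA (T -> U); the oligo module
converts back to DNA at its output edge.
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGUN")

_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


def to_rna(seq: str) -> str:
    """Uppercase and re-encode T as U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and re-encode U as T."""
    return seq.upper().replace("U", "T")


def validate_rna(seq: str, *, context: str = "sequence") -> str:
    seq = to_rna(seq)
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return seq


def revcomp_rna(seq: str) -> str:
    return seq.translate(_COMPLEMENT_RNA)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT_DNA)[::-1]


def complement_rna(nt: str) -> str:
    return nt.translate(_COMPLEMENT_RNA)
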