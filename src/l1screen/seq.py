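"""Small shared nucleotide-string helpers."""

from __future__ import annotations

import numpy as np

__all__ = [
    "revcomp",
    "hamming",
    "at_fraction",
    "validate_alphabet",
    "random_seq",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings; any position with a
    non-ACGT base counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    ok = set("ACGT")
    return sum(
        1 for x, y in zip(a.upper(), b.upper())
        if x != y or x not in ok or y not in ok
    )


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("A") + s.count("T")) / len(s)


def validate_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    """I.i.d. nucleotides at GC fraction ``gc``."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))
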