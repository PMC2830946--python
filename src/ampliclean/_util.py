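"""Small shared DNA helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings.

    With ``limit`` set, returns early with ``limit`` as soon as the count
    reaches it (the caller only needs to know the threshold was crossed).
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if limit is not None and n >= limit:
                return n
    return n


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    return bool(seq) and set(seq) <= alphabet
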