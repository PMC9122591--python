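"""Small nucleotide-sequence helpers shared across the package.

Sequences are handled in the DNA alphabet internally (T on disk); RNA input
(U) is accepted everywhere and normalized on entry.
"""

from __future__ import annotations

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize(seq: str) -> str:
    """Uppercase and convert U -> T. Raises on non-nucleotide characters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET - {"N"}
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N self-complementary)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run."""
    best = run = 0
    prev = None
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best
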