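"""IUPAC nucleotide codes as bitmasks over {A, C, G, T}.

Every code is the set of pure bases it denotes; set operations on the
masks implement ambiguity-aware matching. The gap character ``-`` maps
to the empty set (mask 0) and is handled explicitly by callers.
"""

from __future__ import annotations

import numpy as np

A, C, G, T = 1, 2, 4, 8

#: code -> bitmask of the pure bases it denotes
MASK: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T,
    "R": A | G, "Y": C | T, "S": C | G, "W": A | T,
    "K": G | T, "M": A | C,
    "B": C | G | T, "D": A | G | T, "H": A | C | T, "V": A | C | G,
    "N": A | C | G | T,
    "-": 0,
}

GAP = "-"
PURE_BASES = frozenset("ACGT")
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")
ALPHABET = frozenset(MASK)

#: Watson-Crick complement, closed over the ambiguity codes
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "-": "-",
}

# byte-indexed lookup table for fast sequence encoding
_ENC = np.zeros(256, dtype=np.uint8)
for _sym, _m in MASK.items():
    _ENC[ord(_sym)] = _m
_VALID = np.zeros(256, dtype=bool)
for _sym in MASK:
    _VALID[ord(_sym)] = True


def normalize(seq: str) -> str:
    """Uppercase a sequence and map RNA ``U`` to ``T``."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as a uint8 bitmask vector (gap -> 0)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def first_illegal(seq: str) -> int | None:
    """0-based index of the first character outside the alphabet, or None."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = np.flatnonzero(~_VALID[raw])
    return int(bad[0]) if bad.size else None


def is_ambiguity(symbol: str) -> bool:
    return symbol in AMBIGUITY_CODES


def sets_intersect(a: str, b: str) -> bool:
    """Lenient residue match: the two codes denote overlapping base sets."""
    return bool(MASK[a] & MASK[b])


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[s] for s in reversed(seq))
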