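"""Canonical k-mer primitives.

Nodes of the de Bruijn graph are canonical k-mers: the lexicographically
smaller of a nucleotide word and its reverse complement, so that graph
membership is strand-symmetric.  Reads are split at any non-ACGT symbol;
windows covering such a symbol yield no k-mer.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "revcomp",
    "canonical",
    "kmerize",
    "kmer_positions",
    "encode_codes",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

# byte-code lookup: A,C,G,T -> 0..3, everything else -> 9 (invalid)
_CODE_LUT = np.full(256, 9, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
    _CODE_LUT[_b + 32] = _i  # lowercase

_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGT only)."""
    return seq.translate(_COMP)[::-1]


def is_acgt(seq: str) -> bool:
    return not (set(seq) - _ACGT)


def canonical(word: str) -> str:
    """Canonical form of ``word``: min(word, revcomp(word)) lexicographically.

    Raises ``ValueError`` on non-ACGT symbols; callers split reads at such
    positions instead of creating k-mers over them.
    """
    if not is_acgt(word):
        raise ValueError(f"non-ACGT symbol in k-mer: {word!r}")
    rc = word.translate(_COMP)[::-1]
    return word if word <= rc else rc


def encode_codes(seq: str) -> np.ndarray:
    """Map a sequence to uint8 codes A,C,G,T -> 0..3; invalid symbols -> 9."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[raw]


def kmer_positions(seq: str, k: int) -> np.ndarray:
    """Boolean vector over start positions 0..len-k marking valid windows.

    A window is valid iff every base inside it is one of ACGT.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(seq)
    if n < k:
        return np.zeros(0, dtype=bool)
    bad = (encode_codes(seq) > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    return cs[k:] == cs[: n - k + 1]


def kmerize(seq: str, k: int) -> list[str]:
    """Ordered canonical k-mers of ``seq``, one per valid start position."""
    valid = kmer_positions(seq, k)
    out = []
    comp = _COMP
    for i in np.flatnonzero(valid):
        w = seq[i : i + k].upper()
        rc = w.translate(comp)[::-1]
        out.append(w if w <= rc else rc)
    return out
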