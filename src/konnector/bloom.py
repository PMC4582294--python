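"""Bloom filters over k-mers and the two-level (cascading) occurrence filter.

The de Bruijn graph node set is the *second* level of a cascading Bloom
filter: k-mers seen at least twice in the (quality-trimmed) input reads.
Level one holds k-mers seen at least once and is discarded after loading,
which screens out the bulk of sequencing-error k-mers, since at typical
error rates an erroneous k-mer is almost always a singleton.

Hashing is strand-symmetric by construction: the hash of a word is the sum
(mod 2^64) of a polynomial hash of the word and of its reverse complement,
so a k-mer and its reverse complement always map to the same bit positions.
All seeds and multipliers are fixed constants, making filter files
bit-reproducible across runs and machines.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from functools import lru_cache
from operator import mul

import numpy as np

from .kmer import encode_codes

__all__ = ["BloomFilter", "CascadingBloomFilter", "load_reads", "trim_read"]

_MASK64 = (1 << 64) - 1

# fixed hashing constants (odd multipliers; arbitrary but frozen so that
# serialized filters are reproducible)
_MULT_A = 0x5851F42D4C957F2D
_MULT_B = 0x9E3779B97F4A7C15 | 1
_SEED_A = 0x243F6A8885A308D3
_SEED_B = 0x13198A2E03707344

MAGIC = b"KONBLOOM"
FORMAT_VERSION = 1


def _splitmix64(x: int) -> int:
    z = (x + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def _splitmix64_vec(x: np.ndarray) -> np.ndarray:
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


class _PolyTable:
    """Per-(k, multiplier) coefficient table for the strand-symmetric hash.

    For a window of base codes c_0..c_{k-1} the orientation-symmetric value is

        u = sum_j c_j * a^(k-1-j)  +  sum_j (3 - c_j) * a^j      (mod 2^64)
          = const + sum_j c_j * (a^(k-1-j) - a^j)                (mod 2^64)

    i.e. the polynomial hash of the word plus the polynomial hash of its
    reverse complement; a single dot product per window suffices.
    """

    def __init__(self, k: int, mult: int):
        desc = [pow(mult, k - 1 - j, 1 << 64) for j in range(k)]
        asc = [pow(mult, j, 1 << 64) for j in range(k)]
        self.diff = [(d - a) & _MASK64 for d, a in zip(desc, asc)]
        self.const = (3 * sum(asc)) & _MASK64
        self.diff_vec = np.array(self.diff, dtype=np.uint64)


_tables: dict[tuple[int, int], _PolyTable] = {}


def _table(k: int, mult: int) -> _PolyTable:
    key = (k, mult)
    t = _tables.get(key)
    if t is None:
        t = _tables[key] = _PolyTable(k, mult)
    return t


_CODE_OF = {"A": 0, "C": 1, "G": 2, "T": 3, "a": 0, "c": 1, "g": 2, "t": 3}


@lru_cache(maxsize=1 << 18)
def hash_pair(word: str) -> tuple[int, int]:
    """The two 64-bit strand-symmetric hash values of a k-mer word.

    Cached: graph traversal re-queries the same words constantly (bursts of
    read pairs cover overlapping genomic windows).
    """
    k = len(word)
    ta, tb = _table(k, _MULT_A), _table(k, _MULT_B)
    codes = [_CODE_OF[c] for c in word]
    ua = (ta.const + sum(map(mul, codes, ta.diff))) & _MASK64
    ub = (tb.const + sum(map(mul, codes, tb.diff))) & _MASK64
    return ua, ub


def hash_pairs_of_sequence(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window hashes of ``seq``.

    Returns ``(ua, ub, valid)`` where ``ua``/``ub`` are uint64 arrays over
    all start positions ``0..len(seq)-k`` and ``valid`` marks windows free
    of non-ACGT symbols.  Bit-identical to :func:`hash_pair` per window.
    """
    n = len(seq)
    nwin = n - k + 1
    if nwin <= 0:
        z = np.zeros(0, dtype=np.uint64)
        return z, z.copy(), np.zeros(0, dtype=bool)
    codes = encode_codes(seq)
    bad = (codes > 3).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = cs[k:] == cs[:nwin]

    codes64 = codes.astype(np.uint64)
    ta, tb = _table(k, _MULT_A), _table(k, _MULT_B)
    ua = np.empty(nwin, dtype=np.uint64)
    ub = np.empty(nwin, dtype=np.uint64)
    # block the sliding-window dot product to bound the temporary to ~64 MB
    block = max(1, (8 << 20) // max(k, 1))
    win = np.lib.stride_tricks.sliding_window_view(codes64, k)
    for lo in range(0, nwin, block):
        hi = min(lo + block, nwin)
        w = win[lo:hi]
        ua[lo:hi] = (w * ta.diff_vec).sum(axis=1, dtype=np.uint64)
        ub[lo:hi] = (w * tb.diff_vec).sum(axis=1, dtype=np.uint64)
    ua += np.uint64(ta.const)
    ub += np.uint64(tb.const)
    return ua, ub, valid


@dataclass
class BloomFilter:
    """Plain Bloom filter over nucleotide words with strand-symmetric hashing.

    No false negatives; false-positive rate approximately
    ``(1 - exp(-h*n/m))**h`` for ``n`` distinct insertions.
    """

    m: int
    h: int
    n_inserted: int = 0
    bits: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        if self.m < 8:
            raise ValueError("filter size m must be >= 8 bits")
        if self.h < 1:
            raise ValueError("need at least one hash function")
        if self.bits is None:
            self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)

    # -- scalar path -------------------------------------------------------
    def _indices(self, ua: int, ub: int):
        h1 = _splitmix64(ua ^ _SEED_A)
        h2 = _splitmix64(ub ^ _SEED_B) | 1
        m = self.m
        return [((h1 + i * h2) & _MASK64) % m for i in range(self.h)]

    def insert(self, word: str) -> None:
        ua, ub = hash_pair(word)
        bits = self.bits
        for idx in self._indices(ua, ub):
            bits[idx >> 3] |= np.uint8(1 << (idx & 7))
        self.n_inserted += 1

    def contains(self, word: str) -> bool:
        ua, ub = hash_pair(word)
        bits = self.bits
        for idx in self._indices(ua, ub):
            if not (int(bits[idx >> 3]) >> (idx & 7)) & 1:
                return False
        return True

    # -- vector path -------------------------------------------------------
    def _indices_vec(self, ua: np.ndarray, ub: np.ndarray) -> np.ndarray:
        h1 = _splitmix64_vec(ua ^ np.uint64(_SEED_A))
        h2 = _splitmix64_vec(ub ^ np.uint64(_SEED_B)) | np.uint64(1)
        i = np.arange(self.h, dtype=np.uint64)[:, None]
        return (h1[None, :] + i * h2[None, :]) % np.uint64(self.m)

    def insert_hashes(self, ua: np.ndarray, ub: np.ndarray) -> None:
        if ua.size == 0:
            return
        idx = self._indices_vec(ua, ub).ravel()
        np.bitwise_or.at(self.bits, (idx >> np.uint64(3)).astype(np.int64),
                         (np.uint64(1) << (idx & np.uint64(7))).astype(np.uint8))
        self.n_inserted += int(ua.size)

    def contains_hashes(self, ua: np.ndarray, ub: np.ndarray) -> np.ndarray:
        if ua.size == 0:
            return np.zeros(0, dtype=bool)
        idx = self._indices_vec(ua, ub)
        got = (self.bits[(idx >> np.uint64(3)).astype(np.int64)]
               >> (idx & np.uint64(7)).astype(np.uint8)) & 1
        return got.all(axis=0)

    # -- diagnostics -------------------------------------------------------
    def expected_fpr(self, n: int | None = None) -> float:
        n = self.n_inserted if n is None else n
        return (1.0 - math.exp(-self.h * n / self.m)) ** self.h

    def __eq__(self, other) -> bool:  # bit-exact comparison
        return (isinstance(other, BloomFilter) and self.m == other.m
                and self.h == other.h and self.n_inserted == other.n_inserted
                and bool(np.array_equal(self.bits, other.bits)))


class CascadingBloomFilter:
    """Two-level occurrence filter: level 1 = seen >= 1, level 2 = seen >= 2.

    After read loading completes, level 1 may be discarded
    (:meth:`drop_level1`); all downstream graph queries hit level 2 only.
    """

    def __init__(self, k: int, m: int, h: int, levels: int = 2):
        if levels != 2:
            raise ValueError("only the two-level cascade is supported")
        self.k = k
        self.levels = levels
        self.level1: BloomFilter | None = BloomFilter(m, h)
        self.level2 = BloomFilter(m, h)

    def insert(self, word: str) -> None:
        if self.level1 is None:
            raise RuntimeError("level 1 already discarded; filter is frozen")
        if self.level1.contains(word):
            self.level2.insert(word)
        else:
            self.level1.insert(word)

    def insert_batch(self, ua: np.ndarray, ub: np.ndarray) -> None:
        """Cascade-insert a batch of window hashes.

        Within-batch repeats are promoted to level 2 exactly as sequential
        insertion would do: an element goes to level 2 iff it was already in
        level 1 before the batch or is a repeat inside the batch.
        """
        if self.level1 is None:
            raise RuntimeError("level 1 already discarded; filter is frozen")
        if ua.size == 0:
            return
        in_l1 = self.level1.contains_hashes(ua, ub)
        order = np.lexsort((ub, ua))
        sa, sb = ua[order], ub[order]
        rep_sorted = np.zeros(ua.size, dtype=bool)
        rep_sorted[1:] = (sa[1:] == sa[:-1]) & (sb[1:] == sb[:-1])
        repeat = np.zeros(ua.size, dtype=bool)
        repeat[order] = rep_sorted
        to_l2 = in_l1 | repeat
        self.level1.insert_hashes(ua[~in_l1 & ~repeat], ub[~in_l1 & ~repeat])
        self.level2.insert_hashes(ua[to_l2], ub[to_l2])

    def contains(self, word: str) -> bool:
        """Level-2 membership: the k-mer was seen at least twice."""
        return self.level2.contains(word)

    def drop_level1(self) -> None:
        self.level1 = None

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Write the bit-exact on-disk format (little-endian header + bits)."""
        stored = [(1, self.level1), (2, self.level2)]
        stored = [(i, f) for i, f in stored if f is not None]
        with open(path, "wb") as fh:
            fh.write(MAGIC)
            fh.write(struct.pack("<IIII", FORMAT_VERSION, self.k,
                                 self.levels, len(stored)))
            for idx, f in stored:
                raw = f.bits.tobytes()
                fh.write(struct.pack("<IQIQQ", idx, f.m, f.h,
                                     f.n_inserted, len(raw)))
                fh.write(raw)

    @classmethod
    def load(cls, path, expected_k: int | None = None) -> "CascadingBloomFilter":
        with open(path, "rb") as fh:
            magic = fh.read(8)
            if magic != MAGIC:
                raise ValueError(f"{path}: not a KONBLOOM filter file")
            hdr = fh.read(16)
            if len(hdr) != 16:
                raise ValueError(f"{path}: truncated header")
            version, k, levels, n_stored = struct.unpack("<IIII", hdr)
            if version != FORMAT_VERSION:
                raise ValueError(f"{path}: unsupported format version {version}")
            if expected_k is not None and k != expected_k:
                raise ValueError(f"{path}: filter built for k={k}, expected k={expected_k}")
            obj = cls.__new__(cls)
            obj.k, obj.levels = k, levels
            obj.level1 = None
            obj.level2 = None  # type: ignore[assignment]
            for _ in range(n_stored):
                lh = fh.read(32)
                if len(lh) != 32:
                    raise ValueError(f"{path}: truncated level header")
                idx, m, h, n_ins, nbytes = struct.unpack("<IQIQQ", lh)
                raw = fh.read(nbytes)
                if len(raw) != nbytes:
                    raise ValueError(f"{path}: truncated bit array")
                f = BloomFilter(m, h, n_inserted=n_ins,
                                bits=np.frombuffer(raw, dtype=np.uint8).copy())
                if idx == 1:
                    obj.level1 = f
                elif idx == 2:
                    obj.level2 = f
            if obj.level2 is None:
                raise ValueError(f"{path}: no level-2 filter present")
            return obj

    def __eq__(self, other) -> bool:
        return (isinstance(other, CascadingBloomFilter) and self.k == other.k
                and self.levels == other.levels and self.level1 == other.level1
                and self.level2 == other.level2)


def trim_read(seq: str, qual: str | None, q: int) -> str:
    """Hard 3' quality trim: truncate at the first base with Phred < q.

    FASTA input (``qual is None``) or ``q <= 0`` disables trimming.
    """
    if qual is None or q <= 0:
        return seq
    for i, c in enumerate(qual):
        if ord(c) - 33 < q:
            return seq[:i]
    return seq


def load_reads(reads, k: int, q: int = 15, bits: int | None = None,
               h: int | None = None, levels: int = 2,
               chunk_bases: int = 2_000_000) -> CascadingBloomFilter:
    """Build the two-level k-mer filter from reads.

    ``reads`` is a sequence of either plain sequences or ``(seq, qual)``
    pairs.  Every k-mer occurring at least twice in the quality-trimmed
    reads ends up in level 2.  If ``bits`` (size of *each* level, in bits)
    is not given, it defaults to 6 bits per k-mer occurrence — 12 bits per
    k-mer across both levels; ``h`` defaults to ``round(ln 2 * bits/n)``
    with a floor of 1.

    Level 1 is retained on the returned filter (so callers may serialize or
    keep cascading); pipelines drop it before graph traversal.
    """
    seqs: list[str] = []
    total_windows = 0
    for r in reads:
        if isinstance(r, str):
            s = r
        else:
            s = trim_read(r[0], r[1], q)
        s = s.upper()
        if len(s) >= k:
            seqs.append(s)
            total_windows += len(s) - k + 1
    if bits is None:
        bits = max(64, 6 * total_windows)
    if h is None:
        n_est = max(1, total_windows)
        h = max(1, round(math.log(2) * bits / n_est))
    cbf = CascadingBloomFilter(k, bits, h, levels=levels)

    buf: list[str] = []
    size = 0

    def flush():
        nonlocal size
        if not buf:
            return
        chunk = "N".join(buf)
        ua, ub, valid = hash_pairs_of_sequence(chunk, k)
        cbf.insert_batch(ua[valid], ub[valid])
        buf.clear()
        size = 0

    for s in seqs:
        buf.append(s)
        size += len(s)
        if size >= chunk_bases:
            flush()
    flush()
    return cbf
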