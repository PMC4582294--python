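"""Sequence extension, unconnected-read correction and duplicate suppression.

Once a pair is connected (or its reads error-corrected), the sequence is
extended outwards in the de Bruijn graph until a dead end or a genuine
branching point, skipping false-positive branches and collapsing simple
SNP bubbles.  Because reads lying on the same linear stretch of the graph
would all extend to the same sequence, a separate "duplicate filter"
Bloom filter tracks the k-mers of everything already emitted, and a
sequence is only emitted when at least one of its query k-mers is new.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anchoring import select_anchor, solid_mask, _runs
from .bloom import BloomFilter, hash_pairs_of_sequence, trim_read
from .graph import GraphHandle
from .kmer import revcomp
from .params import ConnectParams
from .search import ConnectResult, connect_pair, path_to_seq
from .walks import extend_right, linear_walk, surviving_neighbors, try_collapse

__all__ = [
    "DuplicateFilter", "PseudoRead", "extend_seq", "extend_both",
    "collapse_bubble", "correct_unconnected", "is_novel", "register",
    "process_pair",
]


@dataclass(frozen=True)
class PseudoRead:
    """An output sequence with its provenance."""

    seq: str
    provenance: str  # connected | connected_extended | unconnected_extended
    pair_id: str = ""


class DuplicateFilter:
    """Bloom filter over the k-mers of already-emitted sequences."""

    def __init__(self, k: int, m: int, h: int):
        self.k = k
        self.filter = BloomFilter(m, h)

    def is_novel(self, seq: str) -> bool:
        """True iff at least one k-mer of ``seq`` is absent from the filter.

        An empty k-mer list asserts nothing and returns False.
        """
        ua, ub, valid = hash_pairs_of_sequence(seq.upper(), self.k)
        if not valid.any():
            return False
        return not self.filter.contains_hashes(ua[valid], ub[valid]).all()

    def is_novel_kmers(self, kmers) -> bool:
        kmers = list(kmers)
        if not kmers:
            return False
        return any(not self.filter.contains(x) for x in kmers)

    def register(self, seq: str) -> None:
        """Add every k-mer of ``seq`` to the filter."""
        ua, ub, valid = hash_pairs_of_sequence(seq.upper(), self.k)
        self.filter.insert_hashes(ua[valid], ub[valid])


def is_novel(d: DuplicateFilter, kmers) -> bool:
    return d.is_novel_kmers(kmers)


def register(d: DuplicateFilter, seq: str) -> None:
    d.register(seq)


# ---------------------------------------------------------------------------

def _seed_anchor(g: GraphHandle, seq: str):
    """Anchor near the 3' end of ``seq`` for seeding an extension walk."""
    k = g.k
    window = min(len(seq), k + 33)
    tail = seq[len(seq) - window:]
    a = select_anchor(g, tail)
    if a is None:
        return None
    return a.kmer, len(seq) - window + a.offset


def _extend_seq_right(g: GraphHandle, seq: str,
                      max_extension: int | None) -> str:
    seeded = _seed_anchor(g, seq)
    if seeded is None:
        return seq
    word, off = seeded
    retrace = len(seq) - (off + g.k)
    cap = None if max_extension is None else retrace + max_extension
    bases = extend_right(g, word, max_bases=cap)
    if len(bases) <= retrace:
        return seq
    return seq + bases[retrace:]


def extend_seq(g: GraphHandle, seq: str, direction: str,
               max_extension: int | None = None) -> str:
    """Extend ``seq`` in one direction to the next dead end or genuine fork.

    The walk is seeded anchor-style near the relevant end (so a terminal
    error or Bloom false positive cannot strand it), skips false-positive
    branches, collapses reconverging two-branch bubbles, and never revisits
    a node within the current walk.  A zero-length extension is valid.
    """
    if direction == "right":
        return _extend_seq_right(g, seq, max_extension)
    if direction == "left":
        return revcomp(_extend_seq_right(g, revcomp(seq), max_extension))
    raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")


def extend_both(g: GraphHandle, seq: str, params: ConnectParams) -> str:
    out = extend_seq(g, seq, "right", params.max_extension)
    return extend_seq(g, out, "left", params.max_extension)


def collapse_bubble(g: GraphHandle, fork_node: str, direction: str) -> str | None:
    """Continuation node of a collapsible two-branch bubble at ``fork_node``.

    Returns the reconvergence node if the two surviving branches re-join at
    the same depth within a k+1-node look-ahead, else None (including for
    forks with more than two surviving branches).
    """
    branches = surviving_neighbors(g, fork_node, direction)
    if len(branches) != 2:
        return None
    res = try_collapse(g, branches, direction)
    if res is None:
        return None
    nodes, _bases = res
    return nodes[-1]


def correct_unconnected(g: GraphHandle, read: str) -> str | None:
    """High-confidence sequence from an unconnectable read, or None.

    Takes the longest run of solid k-mers (ties toward the 3' end); from
    its rightmost k-mer walks left exactly k linear nodes — enough to exit
    any branch or bubble a single recurrent read error can create — then
    walks right up to k+1 nodes, stopping early at a fork or dead end but
    keeping the sequence built so far.  The left walk aborts the whole
    correction if it cannot complete.
    """
    k = g.k
    read = read.upper()
    mask = solid_mask(g, read)
    runs = _runs(mask)
    if not runs:
        return None
    run = max(runs, key=lambda r: (r[1] - r[0], r[1]))
    off = run[1]
    word = read[off : off + k]
    left = linear_walk(g, word, "left", k)
    if left is None or len(left) < k:
        return None
    right = linear_walk(g, word, "right", k + 1, stop_early=True) or []
    nodes = list(reversed(left)) + [word] + right
    return path_to_seq(nodes)


# ---------------------------------------------------------------------------

def process_pair(g: GraphHandle, dup: DuplicateFilter | None, read1: str,
                 read2: str, params: ConnectParams, extend_enabled: bool = True,
                 pair_id: str = "", qual1: str | None = None,
                 qual2: str | None = None) -> tuple[list[PseudoRead], ConnectResult]:
    """Full per-pair flow: connect, deduplicate, correct, extend.

    Connected pairs query the duplicate filter with the k-mers of the
    connecting sequence only (those are putative non-error k-mers, so a
    100% hit is expected for an already-covered locus); novel ones are
    extended in both directions, registered, and emitted.  Unconnected
    pairs have each read corrected and treated the same way, read 1 before
    read 2 (so read 2's novelty is tested after read 1's registration).
    With extension disabled the behaviour reverts to one pseudo-read per
    connected pair and no duplicate suppression.
    """
    res = connect_pair(g, read1, read2, params, qual1=qual1, qual2=qual2)
    if res.connected:
        if not extend_enabled:
            return [PseudoRead(res.pseudo_read, "connected", pair_id)], res
        if dup is not None and not dup.is_novel(res.connecting_seq):
            return [], res
        ext = extend_both(g, res.pseudo_read, params)
        if dup is not None:
            dup.register(ext)
        return [PseudoRead(ext, "connected_extended", pair_id)], res
    out: list[PseudoRead] = []
    if extend_enabled:
        for idx, (r, ql) in enumerate(((read1, qual1), (read2, qual2)), 1):
            rt = trim_read(r.upper(), ql, params.q)
            if len(rt) < params.k:
                continue
            hc = correct_unconnected(g, rt)
            if hc is None:
                continue
            if dup is not None and not dup.is_novel(hc):
                continue
            ext = extend_both(g, hc, params)
            if dup is not None:
                dup.register(ext)
            out.append(PseudoRead(ext, "unconnected_extended",
                                  f"{pair_id}/{idx}" if pair_id else str(idx)))
    return out, res
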