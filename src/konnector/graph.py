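"""Implicit de Bruijn graph over the level-2 k-mer filter.

Nodes are canonical k-mers; edges are never stored.  Traversal carries an
*oriented* word (the strand the walk is on) and queries the four possible
single-base extensions for membership, so left/right are always relative to
the oriented word and palindromic k-mers cannot silently reverse a walk.
"""

from __future__ import annotations

from .bloom import CascadingBloomFilter
from .kmer import canonical, revcomp

__all__ = ["GraphHandle", "BloomGraph", "ExactSetGraph", "classify_node"]

_BASES = "ACGT"


class GraphHandle:
    """Membership + neighbor queries; node set = the backing k-mer set."""

    k: int

    def contains(self, word: str) -> bool:
        """Strand-symmetric membership of the k-mer ``word``."""
        raise NotImplementedError

    def neighbors(self, word: str, direction: str) -> list[str]:
        """Oriented single-base extensions of ``word`` present in the graph.

        ``direction='right'`` yields words ``word[1:] + b``;
        ``'left'`` yields ``b + word[:-1]``; 0-4 results, in A<C<G<T order.
        """
        out = []
        if direction == "right":
            stem = word[1:]
            for b in _BASES:
                cand = stem + b
                if self.contains(cand):
                    out.append(cand)
        elif direction == "left":
            stem = word[:-1]
            for b in _BASES:
                cand = b + stem
                if self.contains(cand):
                    out.append(cand)
        else:
            raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
        return out


class BloomGraph(GraphHandle):
    """De Bruijn graph backed by the level-2 Bloom filter (may have rare
    false-positive nodes, never false-negative ones)."""

    def __init__(self, filt: CascadingBloomFilter):
        self.filter = filt
        self.k = filt.k

    def contains(self, word: str) -> bool:
        return self.filter.contains(word)


class ExactSetGraph(GraphHandle):
    """Exact hash-set graph, interchangeable with :class:`BloomGraph`.

    Zero false positives; used as the test oracle and for fixtures where
    Bloom noise would obscure the property under test.
    """

    def __init__(self, kmers, k: int):
        self.k = k
        self.kmers = {canonical(x) for x in kmers}

    @classmethod
    def from_sequences(cls, seqs, k: int) -> "ExactSetGraph":
        from .kmer import kmerize
        ks: set[str] = set()
        for s in seqs:
            ks.update(kmerize(s, k))
        return cls(ks, k)

    def contains(self, word: str) -> bool:
        rc = revcomp(word)
        return (word if word <= rc else rc) in self.kmers


def classify_node(g: GraphHandle, word: str, direction: str) -> str:
    """``dead_end`` (0 neighbors), ``linear`` (1) or ``branching`` (>= 2)."""
    n = len(g.neighbors(word, direction))
    if n == 0:
        return "dead_end"
    if n == 1:
        return "linear"
    return "branching"
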