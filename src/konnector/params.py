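"""Tunable parameters of the connection algorithm."""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["ConnectParams"]


@dataclass(frozen=True)
class ConnectParams:
    """All tunables of the read-pair connection algorithm.

    Attributes
    ----------
    k : k-mer length (graph node size).
    B : maximum branches visited during the bidirectional search; every
        dequeued node beyond the first at any fork counts, summed over both
        frontiers.
    F : maximum fragment (pseudo-read) length in bp; sets the search depth
        limit.
    P : maximum number of alternate connecting paths merged into a consensus.
    M : maximum mismatches tolerated between alternate paths; ``None`` means
        no limit.
    X : minimum percent identity between alternate paths (0-100).
    q : 3' quality-trim threshold (Phred); 0 disables trimming.
    levels : depth of the Bloom cascade (2: graph k-mers are those seen
        at least twice).
    correct_flanks : spell the read bases outside the anchors from the graph
        (linear walk outward from each anchor) instead of emitting them
        verbatim; falls back to verbatim bases where the walk is blocked.
    max_extension : cap, in bp per direction, on sequence extension;
        ``None`` extends to the next branching point or dead end.
    """

    k: int = 31
    B: int = 100
    F: int = 525
    P: int = 4
    M: int | None = None
    X: float = 98.0
    q: int = 15
    levels: int = 2
    correct_flanks: bool = True
    max_extension: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.F <= 2 * self.k:
            raise ValueError("F must exceed 2*k")
        if self.P < 1:
            raise ValueError("P must be >= 1")
        if not (0.0 <= self.X <= 100.0):
            raise ValueError("X must be a percentage in [0, 100]")
        if self.levels != 2:
            raise ValueError("only the two-level Bloom cascade is supported")

    def with_k(self, k: int) -> "ConnectParams":
        return replace(self, k=k)
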