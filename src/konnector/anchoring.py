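"""Anchor (start/goal k-mer) selection.

Path searches are launched from trusted sequence: a run of at least three
consecutive solid k-mers (k-mers present in the graph).  The run closest to
the 3' (gap-facing) end of the read is preferred, and the anchor is the
5'-most k-mer of that run, so that even if the anchor itself is a Bloom
false positive the search proceeds through at least two more solid k-mers
before it can dead-end.  When no run of three exists, the longest run found
is used (ties broken toward the 3' end).
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import GraphHandle
from .kmer import kmer_positions, revcomp

__all__ = ["Anchor", "solid_mask", "select_anchor"]


@dataclass(frozen=True)
class Anchor:
    kmer: str      # oriented as in the read
    offset: int    # 0-based start of the k-mer in the read
    run_len: int   # length (in k-mers) of the solid run it belongs to


def solid_mask(g: GraphHandle, read: str) -> list[bool]:
    """Per-position solidity: True iff the k-mer starting there is in the graph.

    Positions whose window covers a non-ACGT base are False.  Empty for
    reads shorter than k.
    """
    k = g.k
    valid = kmer_positions(read, k)
    mask = []
    for i, ok in enumerate(valid):
        mask.append(bool(ok) and g.contains(read[i : i + k].upper()))
    return mask


def _runs(mask) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def select_anchor(g: GraphHandle, read: str) -> Anchor | None:
    """Choose the search anchor of a read oriented 3'-toward-the-gap.

    Among runs of >= 3 solid k-mers, pick the run whose 3'-most k-mer lies
    closest to the 3' end; the anchor is the 5'-most k-mer of that run.
    With no such run, fall back to the longest run (ties toward 3').
    Returns None when the read has no solid k-mer at all.
    """
    mask = solid_mask(g, read)
    runs = _runs(mask)
    if not runs:
        return None
    good = [r for r in runs if r[1] - r[0] + 1 >= 3]
    if good:
        run = max(good, key=lambda r: r[1])
    else:
        run = max(runs, key=lambda r: (r[1] - r[0], r[1]))
    start, end = run
    k = g.k
    return Anchor(kmer=read[start : start + k], offset=start,
                  run_len=end - start + 1)


def anchor_on_rc(read: str, anchor: Anchor, k: int) -> tuple[str, int]:
    """Map a read-oriented anchor onto the reverse-complemented read.

    Returns the oriented anchor word on the opposite strand and its offset
    within ``revcomp(read)``.
    """
    rc = revcomp(read)
    off = len(read) - anchor.offset - k
    return rc[off : off + k], off
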