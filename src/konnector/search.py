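"""Connecting-path search between the anchors of a read pair.

A depth-limited, bidirectional breadth-first search is run between the
start anchor (from read 1) and the goal anchor (from read 2, mapped onto
the fragment's forward strand).  All paths — not just the shortest — are
wanted, because the consensus of every connecting path is what guards the
output against picking an arbitrary route through a tangle; this is why a
breadth-first search is used rather than Dijkstra/A*.

The two frontiers strictly alternate one level at a time (forward first).
A node generated by one frontier that was already visited by the other is
recorded as a *common edge* and not expanded further.  All visited nodes
form an in-memory search graph from which the full set of connecting
paths is enumerated exhaustively, then collapsed to a consensus sequence.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

from .anchoring import Anchor, select_anchor
from .bloom import trim_read
from .graph import GraphHandle
from .kmer import revcomp
from .params import ConnectParams
from .walks import linear_walk

__all__ = [
    "SearchFailure", "SearchGraph", "ConnectResult",
    "bidi_bfs", "enumerate_paths", "path_to_seq", "consensus", "connect_pair",
    "NO_ANCHOR", "NO_PATH", "TOO_MANY_BRANCHES", "TOO_MANY_PATHS",
    "PATHS_DISAGREE", "FAILURE_REASONS",
]

NO_ANCHOR = "no_anchor"
NO_PATH = "no_path"
TOO_MANY_BRANCHES = "too_many_branches"
TOO_MANY_PATHS = "too_many_paths"
PATHS_DISAGREE = "paths_disagree"
FAILURE_REASONS = (NO_ANCHOR, NO_PATH, TOO_MANY_BRANCHES, TOO_MANY_PATHS,
                   PATHS_DISAGREE)

_BASES = "ACGT"


class SearchFailure(Exception):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class SearchGraph:
    """Visited-node record of a bidirectional BFS plus its common edges."""

    start: str
    goal: str
    depth_limit: int
    visited_fwd: dict[str, int] = field(default_factory=dict)
    visited_rev: dict[str, int] = field(default_factory=dict)
    common_edges: set[tuple[str, str]] = field(default_factory=set)
    branches_visited: int = 0
    degenerate: bool = False  # start == goal

    @property
    def allowed(self) -> set[str]:
        return set(self.visited_fwd) | set(self.visited_rev)


def bidi_bfs(g: GraphHandle, start: str, goal: str, depth_limit: int,
             B: int) -> SearchGraph:
    """Bidirectional BFS from ``start`` (rightward) and ``goal`` (leftward).

    ``depth_limit`` bounds the number of nodes on a connecting path; each
    frontier expands at most ``ceil(depth_limit/2) + 1`` levels.  Raises
    :class:`SearchFailure` with reason ``no_path`` when the frontiers
    exhaust without meeting, or ``too_many_branches`` once the number of
    extra nodes dequeued at forks (summed over both frontiers) exceeds B.
    """
    if depth_limit < 1:
        raise SearchFailure(NO_PATH)
    sg = SearchGraph(start=start, goal=goal, depth_limit=depth_limit)
    if start == goal:
        sg.degenerate = True
        sg.visited_fwd[start] = 0
        sg.visited_rev[goal] = 0
        return sg
    cap = math.ceil(depth_limit / 2) + 1
    sg.visited_fwd[start] = 0
    sg.visited_rev[goal] = 0
    frontier_f: deque[str] = deque([start])
    frontier_r: deque[str] = deque([goal])
    level_f = level_r = 0

    def bump_branches(n_nbrs: int) -> None:
        if n_nbrs >= 2:
            sg.branches_visited += n_nbrs - 1
            if sg.branches_visited > B:
                raise SearchFailure(TOO_MANY_BRANCHES)

    while frontier_f or frontier_r:
        # forward level
        if frontier_f and level_f < cap:
            level_f += 1
            nxt: deque[str] = deque()
            for u in frontier_f:
                nbrs = g.neighbors(u, "right")
                bump_branches(len(nbrs))
                for v in nbrs:
                    if v in sg.visited_rev:
                        sg.common_edges.add((u, v))
                    elif v not in sg.visited_fwd:
                        sg.visited_fwd[v] = level_f
                        nxt.append(v)
            frontier_f = nxt
        else:
            frontier_f = deque()
        # reverse level
        if frontier_r and level_r < cap:
            level_r += 1
            nxt = deque()
            for v in frontier_r:
                nbrs = g.neighbors(v, "left")
                bump_branches(len(nbrs))
                for u in nbrs:
                    if u in sg.visited_fwd:
                        sg.common_edges.add((u, v))
                    elif u not in sg.visited_rev:
                        sg.visited_rev[u] = level_r
                        nxt.append(u)
            frontier_r = nxt
        else:
            frontier_r = deque()
    if not sg.common_edges:
        raise SearchFailure(NO_PATH)
    return sg


def enumerate_paths(sg: SearchGraph, P_limit: int) -> list[list[str]]:
    """All start->goal paths of at most ``depth_limit`` nodes.

    The walk is restricted to the nodes of the search graph (adjacency is
    implied by (k-1)-overlap between member k-mers, so no further graph
    queries are needed).  Node revisits are permitted, bounded by the depth
    limit.  Raises ``too_many_paths`` beyond ``P_limit`` and ``no_path``
    when no walk fits within the depth limit.
    """
    if sg.degenerate:
        return [[sg.start]]
    allowed = sg.allowed
    goal = sg.goal
    dl = sg.depth_limit
    paths: list[list[str]] = []
    path = [sg.start]

    def rec(u: str) -> None:
        if u == goal:
            paths.append(list(path))
            if len(paths) > P_limit:
                raise SearchFailure(TOO_MANY_PATHS)
        if len(path) == dl:
            return
        stem = u[1:]
        for b in _BASES:
            v = stem + b
            if v in allowed:
                path.append(v)
                rec(v)
                path.pop()

    rec(sg.start)
    if not paths:
        raise SearchFailure(NO_PATH)
    return paths


def path_to_seq(path: list[str]) -> str:
    """Spell a node path: k + (nodes - 1) bases, consecutive k-1 overlaps."""
    if not path:
        raise ValueError("empty path")
    return path[0] + "".join(p[-1] for p in path[1:])


# ---------------------------------------------------------------------------
# consensus of alternate connecting paths

def needleman_wunsch(a: str, b: str, match: int = 1, mismatch: int = -1,
                     gap: int = -2) -> tuple[str, str]:
    """Global alignment with deterministic trace-back (diagonal > up > left)."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    back: list[bytearray] = []
    for i in range(1, n + 1):
        row = bytearray(m + 1)
        cur = [0] * (m + 1)
        cur[0] = i * gap
        row[0] = 1  # up
        ai = a[i - 1]
        for j in range(1, m + 1):
            d = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            u = prev[j] + gap
            l = cur[j - 1] + gap
            if d >= u and d >= l:
                cur[j], row[j] = d, 0
            elif u >= l:
                cur[j], row[j] = u, 1
            else:
                cur[j], row[j] = l, 2
        back.append(row)
        prev = cur
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = back[i - 1][j] if i > 0 else 2
        if i > 0 and j > 0 and move == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and (j == 0 or move == 1):
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _pairwise_stats(a: str, b: str) -> tuple[int, int]:
    """(mismatch columns incl. gaps, alignment columns) of a vs b."""
    if len(a) == len(b):
        mism = sum(x != y for x, y in zip(a, b))
        return mism, len(a)
    aa, bb = needleman_wunsch(a, b)
    mism = sum(x != y for x, y in zip(aa, bb))
    return mism, len(aa)


def _column_consensus(rows: list[str]) -> str:
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        best = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == best)
        bases = [c for c in winners if c != "-"]
        if bases:  # a base wins any tie against the gap symbol
            out.append(bases[0])
        # gap strictly preferred: column omitted
    return "".join(out)


def _star_msa(seqs: list[str]) -> list[str]:
    """Center-star multiple alignment around the longest sequence."""
    ref = max(seqs, key=lambda s: (len(s), s))
    alns = [needleman_wunsch(ref, s) for s in seqs]
    nref = len(ref)
    ins = [0] * (nref + 1)  # max insertion-run length before each ref position
    for ra, _sa in alns:
        pos = run = 0
        for c in ra:
            if c == "-":
                run += 1
            else:
                ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        ins[nref] = max(ins[nref], run)
    rows = []
    for ra, sa in alns:
        row: list[str] = []
        pos = 0
        block: list[str] = []
        for rc, sc in zip(ra, sa):
            if rc == "-":
                block.append(sc)
            else:
                row.append("".join(block).ljust(ins[pos], "-"))
                row.append(sc)
                block = []
                pos += 1
        row.append("".join(block).ljust(ins[nref], "-"))
        rows.append("".join(row))
    return rows


def consensus(seqs: list[str], M: int | None, X: float) -> str:
    """Consensus of alternate connecting-path sequences.

    A single path is returned verbatim.  Equal-length paths are merged by
    column-wise majority vote (ties to the lexicographically smallest
    base); unequal lengths go through a multiple sequence alignment first.
    Raises ``paths_disagree`` when any pair exceeds ``M`` mismatches
    (``None`` = no limit) or falls below ``X`` percent identity, counting
    gap columns as mismatches.
    """
    if not seqs:
        raise ValueError("no paths to merge")
    if len(seqs) == 1:
        return seqs[0]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            mism, cols = _pairwise_stats(seqs[i], seqs[j])
            identity = 100.0 * (cols - mism) / cols
            if (M is not None and mism > M) or identity < X:
                raise SearchFailure(PATHS_DISAGREE)
    if len({len(s) for s in seqs}) == 1:
        rows = seqs
    else:
        rows = _star_msa(seqs)
    return _column_consensus(rows)


# ---------------------------------------------------------------------------
# read-pair connection

@dataclass
class ConnectResult:
    status: str                       # 'connected' or a failure reason
    pseudo_read: str | None = None    # full joined sequence
    connecting_seq: str | None = None  # anchor-to-anchor consensus
    path_seqs: list[str] = field(default_factory=list)
    anchor1: Anchor | None = None
    anchor2: Anchor | None = None

    @property
    def connected(self) -> bool:
        return self.status == "connected"


def _corrected_left_flank(g: GraphHandle, start: str, raw: str) -> str:
    """Spell the pre-anchor flank from the graph; verbatim on failure."""
    nodes = linear_walk(g, start, "left", len(raw))
    if nodes is None or len(nodes) < len(raw):
        return raw
    return "".join(n[0] for n in reversed(nodes))


def _corrected_right_flank(g: GraphHandle, goal: str, raw: str) -> str:
    nodes = linear_walk(g, goal, "right", len(raw))
    if nodes is None or len(nodes) < len(raw):
        return raw
    return "".join(n[-1] for n in nodes)


def connect_pair(g: GraphHandle, read1: str, read2: str,
                 params: ConnectParams, qual1: str | None = None,
                 qual2: str | None = None) -> ConnectResult:
    """Join a read pair (FR orientation, as sequenced) through the graph.

    The pseudo-read is read1's pre-anchor prefix, the anchor-to-anchor
    connecting consensus, then the post-anchor suffix of revcomp(read2);
    its length never exceeds F.  The bases between the anchors come from
    the graph path, which implicitly error-corrects them; the flanking
    bases are graph-corrected too when ``params.correct_flanks`` is set
    (falling back to the read bases verbatim where the walk is blocked).
    """
    k = params.k
    r1 = trim_read(read1.upper(), qual1, params.q)
    r2 = trim_read(read2.upper(), qual2, params.q)
    a1 = select_anchor(g, r1) if len(r1) >= k else None
    a2 = select_anchor(g, r2) if len(r2) >= k else None
    if a1 is None or a2 is None:
        return ConnectResult(NO_ANCHOR)
    start = a1.kmer
    goal = revcomp(a2.kmer)
    o1, o2 = a1.offset, a2.offset
    depth_limit = params.F - o1 - o2 - k + 1
    try:
        sg = bidi_bfs(g, start, goal, depth_limit, params.B)
        paths = enumerate_paths(sg, params.P)
        seqs = [path_to_seq(p) for p in paths]
        conn = consensus(seqs, params.M, params.X)
    except SearchFailure as e:
        return ConnectResult(e.reason, anchor1=a1, anchor2=a2)
    left = r1[:o1]
    if params.correct_flanks and left:
        left = _corrected_left_flank(g, start, left)
    rc2 = revcomp(r2)
    right = rc2[len(rc2) - o2:] if o2 else ""
    if params.correct_flanks and right:
        right = _corrected_right_flank(g, goal, right)
    pseudo = left + conn + right
    return ConnectResult("connected", pseudo_read=pseudo, connecting_seq=conn,
                         path_seqs=seqs, anchor1=a1, anchor2=a2)
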