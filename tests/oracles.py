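"""Independent brute-force oracles used to check the search machinery.

Everything here queries a plain Python set of canonical k-mers and never
reuses the package's traversal code paths.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canon(s: str) -> str:
    r = rc(s)
    return s if s <= r else r


def genome_kmers(seqs, k: int) -> set[str]:
    out = set()
    for s in seqs:
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                out.add(canon(w))
    return out


def dfs_paths(kmers: set[str], start: str, goal: str, depth_limit: int,
              max_paths: int = 1_000_000) -> list[str] | None:
    """All start->goal walks of <= depth_limit nodes over the full k-mer set.

    Walks proceed rightward, may revisit nodes, and terminate whenever the
    current node is the goal (a walk through the goal and back again is a
    distinct, longer walk).  Returns spelled sequences, or None when more
    than ``max_paths`` walks exist.
    """
    if canon(start) not in kmers or canon(goal) not in kmers:
        return []
    paths: list[str] = []

    def spell(nodes):
        return nodes[0] + "".join(n[-1] for n in nodes[1:])

    stack = [[start]]
    while stack:
        path = stack.pop()
        if path[-1] == goal:
            paths.append(spell(path))
            if len(paths) > max_paths:
                return None
        if len(path) == depth_limit:
            continue
        stem = path[-1][1:]
        for b in _BASES:
            v = stem + b
            if canon(v) in kmers:
                stack.append(path + [v])
    return sorted(paths)


def one_sided_paths(kmers: set[str], start: str, goal: str,
                    depth_limit: int, max_paths: int = 1_000_000):
    """Plain one-sided depth-limited BFS reachability + exhaustive walks.

    Visits every node within depth_limit levels of the start, then
    enumerates walks restricted to the visited set; equivalent to the
    bidirectional construction by the agreement invariant.
    """
    from collections import deque
    visited = {start}
    frontier = deque([start])
    for _ in range(depth_limit - 1):
        nxt: deque[str] = deque()
        for u in frontier:
            for b in _BASES:
                v = u[1:] + b
                if canon(v) in kmers and v not in visited:
                    visited.add(v)
                    nxt.append(v)
        frontier = nxt
    if goal not in visited:
        return []
    sub = {canon(w) for w in visited}
    return dfs_paths(sub, start, goal, depth_limit, max_paths)


def brute_force_anchor(mask: list[bool]) -> int | None:
    """Anchor offset by direct enumeration of the stated selection rule."""
    runs = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            runs.append((i, j - 1))
            i = j
        else:
            i += 1
    if not runs:
        return None
    good = [r for r in runs if r[1] - r[0] + 1 >= 3]
    if good:
        best = None
        for r in good:  # closest to 3' end by the run's rightmost k-mer
            if best is None or r[1] > best[1]:
                best = r
        return best[0]
    best = None
    for r in runs:  # longest; ties toward 3'
        if (best is None
                or (r[1] - r[0], r[1]) > (best[1] - best[0], best[1])):
            best = r
    return best[0]
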