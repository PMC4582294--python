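"""Graph-walk primitives shared by connection, correction and extension.

Implements the look-ahead rules of the traversal logic:

* false-positive-branch skipping — at a fork, any branch through which no
  walk of more than three nodes exists is assumed to be a Bloom filter
  false positive and is ignored;
* linear walks that either abort or truncate at a genuine fork/dead end;
* rightward extension with bubble collapsing — at a fork with exactly two
  surviving branches, a look-ahead of k+1 nodes checks whether the branches
  reconverge (the signature of a heterozygous-SNP bubble); if so the bubble
  is collapsed and the walk continues.
"""

from __future__ import annotations

from .graph import GraphHandle

__all__ = [
    "surviving_neighbors",
    "linear_walk",
    "extend_right",
    "FP_BRANCH_LEN",
]

# branches of at most this many nodes are treated as Bloom false positives
FP_BRANCH_LEN = 3


def _reaches_depth(g: GraphHandle, word: str, direction: str, depth: int) -> bool:
    """True iff some walk of ``depth`` nodes starting at ``word`` exists."""
    if depth <= 1:
        return True
    for v in g.neighbors(word, direction):
        if _reaches_depth(g, v, direction, depth - 1):
            return True
    return False


def surviving_neighbors(g: GraphHandle, word: str, direction: str) -> list[str]:
    """Neighbors of ``word`` after pruning false-positive branches.

    With zero or one neighbor there is nothing to prune (a lone short
    continuation at a chain end is real sequence, not a branch).  At a
    fork, only branches supporting a walk of more than
    :data:`FP_BRANCH_LEN` nodes survive.
    """
    nbrs = g.neighbors(word, direction)
    if len(nbrs) <= 1:
        return nbrs
    return [n for n in nbrs
            if _reaches_depth(g, n, direction, FP_BRANCH_LEN + 1)]


def linear_walk(g: GraphHandle, word: str, direction: str, steps: int,
                stop_early: bool = False) -> list[str] | None:
    """Walk up to ``steps`` linear steps from ``word``.

    Each step requires exactly one surviving neighbor.  On a fork or dead
    end: with ``stop_early`` the nodes walked so far are returned (possibly
    fewer than ``steps``); otherwise the walk aborts and returns ``None``.
    ``word`` itself is not included in the returned node list.
    """
    nodes: list[str] = []
    cur = word
    seen = {word}
    for _ in range(steps):
        nxt = surviving_neighbors(g, cur, direction)
        if len(nxt) != 1 or nxt[0] in seen:
            return nodes if stop_early else None
        cur = nxt[0]
        nodes.append(cur)
        seen.add(cur)
    return nodes


def _arm_walk(g: GraphHandle, word: str, direction: str, steps: int) -> list[str]:
    """Nodes of one bubble arm: linear walk truncated at any fork/dead end."""
    out = linear_walk(g, word, direction, steps, stop_early=True)
    return [word] + (out or [])


def try_collapse(g: GraphHandle, branches: list[str], direction: str
                 ) -> tuple[list[str], str] | None:
    """Attempt to collapse a two-branch bubble.

    Looks ahead k+1 nodes along each arm; if the arms reconverge on the
    same node at the same depth, returns ``(nodes, bases)`` of the
    lexicographically smaller arm up to and including the reconvergence
    node.  Returns None when the branches do not reconverge in range.
    """
    if len(branches) != 2:
        return None
    k = g.k
    arm_a = _arm_walk(g, branches[0], direction, k + 1)
    arm_b = _arm_walk(g, branches[1], direction, k + 1)
    for t in range(min(len(arm_a), len(arm_b))):
        if arm_a[t] == arm_b[t]:
            pick = 0 if direction == "left" else -1
            bases_a = "".join(n[pick] for n in arm_a[: t + 1])
            bases_b = "".join(n[pick] for n in arm_b[: t + 1])
            if bases_b < bases_a:
                return arm_b[: t + 1], bases_b
            return arm_a[: t + 1], bases_a
    return None


def extend_right(g: GraphHandle, word: str, max_bases: int | None = None,
                 visited: set[str] | None = None) -> str:
    """Extend rightward from ``word`` until a dead end or genuine fork.

    False-positive branches are skipped; two-branch bubbles that reconverge
    within k+1 nodes are collapsed (emitting the lexicographically smaller
    arm).  A visited set guards against cycles, and ``max_bases`` (None =
    unlimited) caps the number of appended bases.  Returns the appended
    bases.
    """
    if visited is None:
        visited = set()
    visited.add(word)
    out: list[str] = []
    cur = word
    while max_bases is None or len(out) < max_bases:
        nxt = surviving_neighbors(g, cur, "right")
        if len(nxt) == 1:
            v = nxt[0]
            if v in visited:
                break
            out.append(v[-1])
            visited.add(v)
            cur = v
            continue
        if len(nxt) == 2:
            collapsed = try_collapse(g, nxt, "right")
            if collapsed is None:
                break
            nodes, bases = collapsed
            if any(n in visited for n in nodes):
                break
            out.append(bases)
            visited.update(nodes)
            cur = nodes[-1]
            continue
        break  # dead end or >2 genuine branches
    s = "".join(out)
    if max_bases is not None:
        s = s[:max_bases]
    return s
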