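"""Scaffold gap closing built on the read-pair connection core.

Every run of N in a draft assembly is a target: the flanking sequences on
its 5' and 3' sides are treated as a synthetic read pair (the 3' flank
reverse-complemented, so the pair faces the gap exactly like a sequenced
FR pair), and a connection is attempted over a descending sweep of k-mer
sizes — large k resolves repeats, small k survives thin local coverage.
The first successful k wins, and the closure replaces the gap plus both
flank regions so the patched scaffold contains the closure verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .bloom import load_reads
from .graph import BloomGraph, GraphHandle
from .kmer import revcomp
from .params import ConnectParams
from .search import connect_pair

__all__ = ["GapRecord", "Closure", "find_gaps", "close_gap",
           "patch_scaffolds", "seal", "SEALER_PARAMS", "DEFAULT_K_SWEEP"]

# connection settings of the gap-closing protocol
SEALER_PARAMS = ConnectParams(B=1000, F=700, P=10, M=None, X=98.0,
                              correct_flanks=False)
DEFAULT_K_SWEEP = (90, 80, 70, 60, 50, 40)

_N_RUN = re.compile(r"N+")


@dataclass(frozen=True)
class GapRecord:
    scaffold_id: str
    start: int  # 0-based, half-open N-run coordinates
    end: int
    flank5: str
    flank3: str

    @property
    def flankable(self) -> bool:
        return bool(self.flank5) and bool(self.flank3)


@dataclass
class Closure:
    gap: GapRecord
    seq: str | None = None       # closure spanning flank5 .. flank3
    k_used: int | None = None
    failures: dict[int, str] = field(default_factory=dict)  # k -> reason

    @property
    def closed(self) -> bool:
        return self.seq is not None


def find_gaps(scaffold_id: str, seq: str, flank_len: int = 100
              ) -> list[GapRecord]:
    """Maximal N-runs of a scaffold, left to right, with N-free flanks.

    Flanks are up to ``flank_len`` bases adjacent to the gap, trimmed back
    at the sequence ends and at neighbouring gaps so they never contain N;
    a gap at a sequence boundary gets an empty flank on that side and is
    reported as unflankable.
    """
    seq = seq.upper()
    gaps = []
    for m in _N_RUN.finditer(seq):
        s, e = m.start(), m.end()
        f5 = seq[max(0, s - flank_len) : s]
        cut = f5.rfind("N")
        if cut != -1:
            f5 = f5[cut + 1:]
        f3 = seq[e : e + flank_len]
        cut = f3.find("N")
        if cut != -1:
            f3 = f3[:cut]
        gaps.append(GapRecord(scaffold_id, s, e, f5, f3))
    return gaps


def close_gap(gap: GapRecord, graphs: dict[int, GraphHandle],
              k_sweep, params: ConnectParams = SEALER_PARAMS) -> Closure:
    """Attempt to close one gap over a descending k sweep; first success wins.

    For each k the 5' flank plays read 1 and the reverse complement of the
    3' flank plays read 2.  A successful closure must carry both flank
    anchor k-mers verbatim at its ends (a guard against consensus drift);
    per-k failure reasons are aggregated on the returned record.
    """
    cl = Closure(gap)
    if not gap.flankable:
        cl.failures[0] = "unflankable"
        return cl
    for k in k_sweep:
        if min(len(gap.flank5), len(gap.flank3)) < k + 2:
            cl.failures[k] = "flank_too_short"
            continue
        g = graphs.get(k)
        if g is None:
            cl.failures[k] = "no_filter"
            continue
        p = replace(params, k=k)
        res = connect_pair(g, gap.flank5, revcomp(gap.flank3), p)
        if not res.connected:
            cl.failures[k] = res.status
            continue
        seq = res.pseudo_read
        if not (seq.startswith(gap.flank5[:k]) and seq.endswith(gap.flank3[-k:])):
            cl.failures[k] = "flank_anchor_mismatch"
            continue
        cl.seq, cl.k_used = seq, k
        break
    return cl


def patch_scaffolds(scaffolds: list[tuple[str, str]],
                    closures: list[Closure]
                    ) -> tuple[list[tuple[str, str]], dict]:
    """Splice closures into the scaffolds; untouched gaps stay as-is.

    A closure replaces the span from the start of the 5' flank to the end
    of the 3' flank, so the patched scaffold contains the closure verbatim
    and no base outside replaced spans changes.  The report counts gaps
    total / closed and the success percentage (1 decimal).
    """
    by_scaffold: dict[str, list[Closure]] = {}
    for cl in closures:
        by_scaffold.setdefault(cl.gap.scaffold_id, []).append(cl)
    out = []
    for name, seq in scaffolds:
        patched = seq.upper()
        # right-to-left so earlier coordinates stay valid
        for cl in sorted(by_scaffold.get(name, []),
                         key=lambda c: c.gap.start, reverse=True):
            if not cl.closed:
                continue
            gap = cl.gap
            lo = gap.start - len(gap.flank5)
            hi = gap.end + len(gap.flank3)
            patched = patched[:lo] + cl.seq + patched[hi:]
        out.append((name, patched))
    total = len(closures)
    n_closed = sum(1 for c in closures if c.closed)
    report = {
        "gaps_total": total,
        "gaps_closed": n_closed,
        "percent_closed": round(100.0 * n_closed / total, 1) if total else 0.0,
    }
    return out, report


def build_sweep_graphs(reads, k_sweep, q: int = 15,
                       bits: int | None = None) -> dict[int, BloomGraph]:
    """One Bloom filter de Bruijn graph per k in the sweep, built once."""
    reads = list(reads)
    graphs = {}
    for k in k_sweep:
        cbf = load_reads(reads, k, q=q, bits=bits)
        cbf.drop_level1()
        graphs[k] = BloomGraph(cbf)
    return graphs


def seal(scaffolds: list[tuple[str, str]], reads, k_sweep=DEFAULT_K_SWEEP,
         params: ConnectParams = SEALER_PARAMS, flank_len: int = 100,
         q: int = 15, bits: int | None = None,
         graphs: dict[int, GraphHandle] | None = None):
    """End-to-end gap closing: find gaps, sweep k, patch.

    Returns ``(patched_scaffolds, closures, report)``.
    """
    k_sweep = sorted(set(k_sweep), reverse=True)
    if graphs is None:
        graphs = build_sweep_graphs(reads, k_sweep, q=q, bits=bits)
    closures = []
    for name, seq in scaffolds:
        for gap in find_gaps(name, seq, flank_len=flank_len):
            closures.append(close_gap(gap, graphs, k_sweep, params))
    patched, report = patch_scaffolds(scaffolds, closures)
    return patched, closures, report
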