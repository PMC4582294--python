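"""End-to-end pseudo-read generation and run statistics."""

from __future__ import annotations

from dataclasses import dataclass, field

from .bloom import CascadingBloomFilter, load_reads
from .extend import DuplicateFilter, PseudoRead, process_pair
from .graph import BloomGraph
from .io import read_pairs, write_pseudo_reads
from .params import ConnectParams
from .search import FAILURE_REASONS

__all__ = ["RunStats", "connect_stream", "run_konnector"]


@dataclass
class RunStats:
    """Per-run accounting; ``pairs_connected + sum(failures) == pairs_total``."""

    pairs_total: int = 0
    pairs_connected: int = 0
    connected_emitted: int = 0
    unconnected_emitted: int = 0
    duplicates_suppressed: int = 0
    bases_emitted: int = 0
    failures: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FAILURE_REASONS})

    def check(self) -> None:
        assert self.pairs_connected + sum(self.failures.values()) \
            == self.pairs_total, "per-pair accounting does not balance"

    def as_rows(self) -> list[tuple[str, int]]:
        rows = [
            ("pairs_total", self.pairs_total),
            ("pairs_connected", self.pairs_connected),
            ("connected_emitted", self.connected_emitted),
            ("unconnected_emitted", self.unconnected_emitted),
            ("duplicates_suppressed", self.duplicates_suppressed),
            ("bases_emitted", self.bases_emitted),
        ]
        rows += [(f"failed_{r}", self.failures[r]) for r in FAILURE_REASONS]
        return rows

    def write_tsv(self, path) -> None:
        with open(path, "wt") as fh:
            for key, val in self.as_rows():
                fh.write(f"{key}\t{val}\n")


def connect_stream(graph, pairs, params: ConnectParams, *,
                   extend: bool = True, dup: DuplicateFilter | None = None,
                   all_paths: bool = False):
    """Process an iterable of read pairs; yields nothing, returns everything.

    ``pairs`` yields ``(id, read1, qual1, read2, qual2)`` tuples.  Returns
    ``(pseudo_reads, stats)``; with ``all_paths`` each alternate connecting
    sequence of a multi-path pair is emitted alongside the consensus.
    """
    stats = RunStats()
    out: list[PseudoRead] = []
    for pair_id, r1, q1, r2, q2 in pairs:
        stats.pairs_total += 1
        emitted, res = process_pair(graph, dup, r1, r2, params,
                                    extend_enabled=extend, pair_id=pair_id,
                                    qual1=q1, qual2=q2)
        if res.connected:
            stats.pairs_connected += 1
            if emitted:
                stats.connected_emitted += len(emitted)
            elif extend:
                stats.duplicates_suppressed += 1
            if all_paths and len(res.path_seqs) > 1:
                for i, ps in enumerate(res.path_seqs, 1):
                    out.append(PseudoRead(ps, f"path{i}", pair_id))
        else:
            stats.failures[res.status] += 1
            stats.unconnected_emitted += len(emitted)
        for p in emitted:
            stats.bases_emitted += len(p.seq)
        out.extend(emitted)
    stats.check()
    return out, stats


def _pair_tuples(src1, src2, interleaved):
    for r1, r2 in read_pairs(src1, src2, interleaved=interleaved):
        yield r1.id, r1.seq, r1.qual, r2.seq, r2.qual


def run_konnector(src1, src2=None, *, out_prefix, params: ConnectParams,
                  interleaved: bool = False, extend: bool = True,
                  all_paths: bool = False, bits: int | None = None,
                  dup_bits: int | None = None, bloom_file=None,
                  jobs: int = 1) -> RunStats:
    """Whole-tool run: build/load the graph filter, connect, write outputs.

    Output is deterministic for fixed inputs and flags and independent of
    ``jobs`` (pairs are always processed in input order; the flag exists
    for interface compatibility).  Writes ``<prefix>_pseudoreads.fa`` and
    ``<prefix>_stats.tsv``.
    """
    del jobs  # output must not depend on worker count
    if bloom_file is not None:
        cbf = CascadingBloomFilter.load(bloom_file, expected_k=params.k)
    else:
        reads = []
        for r1, r2 in read_pairs(src1, src2, interleaved=interleaved):
            reads.append((r1.seq, r1.qual))
            reads.append((r2.seq, r2.qual))
        cbf = load_reads(reads, params.k, q=params.q, bits=bits)
    cbf.drop_level1()
    graph = BloomGraph(cbf)
    dup = None
    if extend:
        m = dup_bits if dup_bits is not None else cbf.level2.m
        dup = DuplicateFilter(params.k, m, cbf.level2.h)
    pseudo, stats = connect_stream(
        graph, _pair_tuples(src1, src2, interleaved), params,
        extend=extend, dup=dup, all_paths=all_paths)
    out_prefix = str(out_prefix)
    write_pseudo_reads(pseudo, out_prefix + "_pseudoreads.fa")
    stats.write_tsv(out_prefix + "_stats.tsv")
    return stats
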