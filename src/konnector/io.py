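"""FASTA/FASTQ reading and pseudo-read output."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["ReadRecord", "iter_reads", "read_pairs", "write_fasta",
           "write_pseudo_reads", "read_fasta"]


@dataclass(frozen=True)
class ReadRecord:
    id: str
    seq: str
    qual: str | None = None


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _strip_pair_suffix(name: str) -> str:
    name = name.split()[0] if name.split() else name
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def iter_reads(path) -> Iterator[ReadRecord]:
    """Stream records from a FASTA or FASTQ file, optionally gzipped."""
    with _open_text(path) as fh:
        first = fh.read(1)
        if not first:
            return
        fh.seek(0)
        if first == ">":
            for title, seq in SimpleFastaParser(fh):
                yield ReadRecord(_strip_pair_suffix(title), seq.upper(), None)
        elif first == "@":
            for title, seq, qual in FastqGeneralIterator(fh):
                yield ReadRecord(_strip_pair_suffix(title), seq.upper(), qual)
        else:
            raise ValueError(f"{path}: not FASTA or FASTQ (starts with {first!r})")


def read_pairs(src1, src2=None, interleaved: bool = False
               ) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Yield read pairs from two files or one interleaved file.

    Two-file mode pairs records by file position and raises on a record
    count mismatch; interleaved mode pairs adjacent records.
    """
    if interleaved or src2 is None:
        it = iter_reads(src1)
        idx = 0
        while True:
            r1 = next(it, None)
            if r1 is None:
                return
            r2 = next(it, None)
            if r2 is None:
                raise ValueError(f"{src1}: odd number of records in "
                                 f"interleaved input (at record {2 * idx})")
            yield r1, r2
            idx += 1
    else:
        it1, it2 = iter_reads(src1), iter_reads(src2)
        idx = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError(f"mate files differ in record count "
                                 f"(at record {idx})")
            yield r1, r2
            idx += 1


def read_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(t.split()[0], s.upper()) for t, s in SimpleFastaParser(fh)]


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_pseudo_reads(pseudo_reads, path, width: int = 60) -> None:
    """Write pseudo-reads as FASTA; headers carry pair id and provenance."""
    write_fasta(((f"{p.pair_id} {p.provenance}", p.seq) for p in pseudo_reads),
                path, width=width)
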