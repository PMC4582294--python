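"""Synthetic genomes, diploid variants and paired-end reads with ground truth.

Emulates the statistical setting the connection algorithm assumes: uniform
random genomes, FR paired-end libraries with normally distributed fragment
lengths, i.i.d. substitution errors, and (optionally) a second haplotype
carrying heterozygous SNPs.  Defaults mirror the synthetic benchmark
conditions: 0.1% substitution error, 50-fold coverage and 400 +- 50 bp
inserts of 100 bp reads.  Every draw comes from a single seeded PCG64
stream, so fixtures are fully deterministic per seed, and the truth table
records exact fragment coordinates so connection output can be scored by
string equality with no aligner in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer import revcomp

__all__ = [
    "SimConfig", "ReadPair", "random_genome", "simulate_pairs",
    "make_diploid", "mask_windows",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    genome_len: int = 20_000
    frag_mean: float = 400.0
    frag_sd: float = 50.0
    read_len: int = 100
    coverage: float = 50.0
    err_rate: float = 0.001
    het_snp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.err_rate, self.het_snp_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.frag_mean < 2 * self.read_len:
            raise ValueError("frag_mean must be >= 2*read_len for gapped pairs")


@dataclass(frozen=True)
class ReadPair:
    pair_id: str
    read1: str
    read2: str
    frag_start: int
    frag_end: int  # half-open
    haplotype: int = 0

    @property
    def frag_len(self) -> int:
        return self.frag_end - self.frag_start


def random_genome(length: int, seed: int) -> str:
    """I.i.d. uniform ACGT sequence; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _add_errors(read: str, rng: np.random.Generator, err_rate: float) -> str:
    if err_rate <= 0.0:
        return read
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < err_rate)
    for i in hits:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_pairs(genome: str | list[str], cfg: SimConfig) -> list[ReadPair]:
    """FR paired-end reads with exact fragment coordinates.

    Fragment lengths are N(frag_mean, frag_sd) rounded and truncated to
    [2*read_len, genome length]; starts are uniform.  read1 is the
    fragment's 5' prefix, read2 the reverse complement of its 3' suffix.
    Substitution errors are i.i.d. per base at ``err_rate``.  The number of
    pairs is ``coverage * genome_len / (2 * read_len)``.  A list of
    haplotype sequences splits the pairs evenly across haplotypes.
    """
    haplotypes = [genome] if isinstance(genome, str) else list(genome)
    glen = len(haplotypes[0])
    if any(len(h) != glen for h in haplotypes):
        raise ValueError("haplotypes must have equal length")
    if glen <= cfg.frag_mean + 4 * cfg.frag_sd:
        raise ValueError("genome too short for the fragment distribution")
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    n_pairs = int(round(cfg.coverage * glen / (2 * cfg.read_len)))
    lens = np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n_pairs))
    lens = np.clip(lens, 2 * cfg.read_len, glen).astype(np.int64)
    out: list[ReadPair] = []
    L = cfg.read_len
    for i in range(n_pairs):
        flen = int(lens[i])
        start = int(rng.integers(0, glen - flen + 1))
        hap = i % len(haplotypes)
        frag = haplotypes[hap][start : start + flen]
        r1 = _add_errors(frag[:L], rng, cfg.err_rate)
        r2 = _add_errors(revcomp(frag[-L:]), rng, cfg.err_rate)
        out.append(ReadPair(pair_id=f"pair{i:06d}", read1=r1, read2=r2,
                            frag_start=start, frag_end=start + flen,
                            haplotype=hap))
    return out


def make_diploid(genome: str, het_snp_rate: float, seed: int
                 ) -> tuple[str, list[tuple[int, str, str]]]:
    """Second haplotype with i.i.d. heterozygous SNPs.

    Returns the alternate haplotype and the variant list (position, ref,
    alt); each listed variant differs between haplotypes at exactly that
    position.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    variants: list[tuple[int, str, str]] = []
    if het_snp_rate > 0.0:
        for i in np.flatnonzero(rng.random(arr.size) < het_snp_rate):
            ref = arr[i]
            alt = rng.choice(_BASES[_BASES != ref])
            arr[i] = alt
            variants.append((int(i), chr(ref), chr(alt)))
    return arr.tobytes().decode("ascii"), variants


def mask_windows(genome: str, n_windows: int, len_range: tuple[int, int],
                 seed: int, min_separation: int = 300,
                 max_tries: int = 100_000
                 ) -> tuple[str, list[tuple[int, int, str]]]:
    """Replace non-overlapping windows with N and keep the truth sequences.

    Windows are kept at least ``min_separation`` bp apart (and away from the
    genome ends) so each gap retains clean flanks.  Raises ``ValueError``
    when the requested packing is infeasible within ``max_tries`` draws.
    Returns the gapped scaffold and ``(start, end, truth)`` per window,
    sorted by start.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    lo, hi = len_range
    if lo < 1 or hi < lo:
        raise ValueError("bad window length range")
    chosen: list[tuple[int, int]] = []
    tries = 0
    while len(chosen) < n_windows:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place the requested windows")
        wlen = int(rng.integers(lo, hi + 1))
        if len(genome) < wlen + 2 * min_separation:
            raise ValueError("genome too short for the requested windows")
        start = int(rng.integers(min_separation,
                                 len(genome) - wlen - min_separation + 1))
        end = start + wlen
        if all(end + min_separation <= s or e + min_separation <= start
               for s, e in chosen):
            chosen.append((start, end))
    chosen.sort()
    arr = list(genome)
    truth = []
    for s, e in chosen:
        truth.append((s, e, genome[s:e]))
        arr[s:e] = "N" * (e - s)
    return "".join(arr), truth
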