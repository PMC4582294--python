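import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from konnector import (BloomGraph, ConnectParams, ExactSetGraph, kmerize,
                       load_reads, random_genome, simulate_pairs)
from konnector.simulate import SimConfig

# fixed study conditions of the synthetic benchmark: 0.1% error, 50x
# coverage, 400 +- 50 bp inserts of paired 100 bp reads
BENCH = dict(frag_mean=400.0, frag_sd=50.0, read_len=100, coverage=50.0)


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(3000, 11)


@pytest.fixture(scope="session")
def small_graph(small_genome):
    return ExactSetGraph(kmerize(small_genome, 21), 21)


def build_bloom_graph(pairs, k, q=0, bits=None):
    reads = []
    for p in pairs:
        reads.append(p.read1)
        reads.append(p.read2)
    cbf = load_reads(reads, k, q=q, bits=bits)
    cbf.drop_level1()
    return BloomGraph(cbf)


@pytest.fixture(scope="session")
def bench20k():
    """20 kb error-free benchmark fixture shared by the acceptance tests."""
    genome = random_genome(20_000, 20_001)
    cfg = SimConfig(genome_len=20_000, err_rate=0.0, seed=20_002, **BENCH)
    pairs = simulate_pairs(genome, cfg)
    graph = build_bloom_graph(pairs, k=31)
    return genome, pairs, graph


@pytest.fixture(scope="session")
def bench20k_err():
    """Same fixture at the benchmark's 0.1% substitution error rate."""
    genome = random_genome(20_000, 20_001)
    cfg = SimConfig(genome_len=20_000, err_rate=0.001, seed=20_003, **BENCH)
    pairs = simulate_pairs(genome, cfg)
    graph = build_bloom_graph(pairs, k=31)
    return genome, pairs, graph


@pytest.fixture()
def params31():
    return ConnectParams(k=31)
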