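import numpy as np
import pytest

from konnector import (ConnectParams, ExactSetGraph, SearchFailure, bidi_bfs,
                       connect_pair, consensus, enumerate_paths, kmerize,
                       path_to_seq, revcomp)
from konnector.search import (NO_PATH, PATHS_DISAGREE, TOO_MANY_BRANCHES,
                              TOO_MANY_PATHS, needleman_wunsch)
from konnector.simulate import SimConfig, random_genome, simulate_pairs

from oracles import dfs_paths, genome_kmers, one_sided_paths


def paths_of(g, start, goal, dl, P=10_000):
    sg = bidi_bfs(g, start, goal, dl, B=10_000)
    return sorted(path_to_seq(p) for p in enumerate_paths(sg, P))


def test_linear_chain_unique_path():
    genome = random_genome(200, 1)
    k = 21
    g = ExactSetGraph(kmerize(genome, k), k)
    start, goal = genome[10:10 + k], genome[150:150 + k]
    dl = 150 - 10 + 1
    sg = bidi_bfs(g, start, goal, dl, B=100)
    assert sg.common_edges
    paths = enumerate_paths(sg, 4)
    assert len(paths) == 1
    assert path_to_seq(paths[0]) == genome[10:150 + k]


def test_degenerate_start_equals_goal():
    genome = random_genome(100, 2)
    g = ExactSetGraph(kmerize(genome, 21), 21)
    w = genome[40:61]
    sg = bidi_bfs(g, w, w, 10, B=10)
    paths = enumerate_paths(sg, 4)
    assert [path_to_seq(p) for p in paths] == [w]


def test_disjoint_components_no_path():
    a, b = random_genome(100, 3), random_genome(100, 4)
    g = ExactSetGraph.from_sequences([a, b], 21)
    with pytest.raises(SearchFailure) as e:
        bidi_bfs(g, a[:21], b[50:71], 120, B=1000)
    assert e.value.reason == NO_PATH


def test_depth_limit_blocks_long_paths():
    genome = random_genome(300, 5)
    g = ExactSetGraph(kmerize(genome, 21), 21)
    with pytest.raises(SearchFailure) as e:
        paths_of(g, genome[:21], genome[200:221], dl=150)
    assert e.value.reason == NO_PATH


def snp_bubble_fixture(k=21, seed=6):
    hap1 = random_genome(200, seed)
    pos = 100
    alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[hap1[pos]]
    hap2 = hap1[:pos] + alt + hap1[pos + 1:]
    g = ExactSetGraph.from_sequences([hap1, hap2], k)
    return g, hap1, hap2, pos


def test_snp_bubble_two_paths():
    g, hap1, hap2, pos = snp_bubble_fixture()
    start, goal = hap1[50:71], hap1[150:171]
    seqs = paths_of(g, start, goal, dl=150 - 50 + 1)
    assert seqs == sorted([hap1[50:171], hap2[50:171]])
    assert sum(a != b for a, b in zip(*seqs)) == 1


def test_parallel_bubbles_exceed_path_limit():
    k = 15
    hap1 = random_genome(400, 8)
    hap2 = list(hap1)
    for pos in (60, 120, 180, 240, 300):  # five isolated bubbles -> 2^5 paths
        hap2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hap1[pos]]
    hap2 = "".join(hap2)
    g = ExactSetGraph.from_sequences([hap1, hap2], k)
    sg = bidi_bfs(g, hap1[20:20 + k], hap1[350:350 + k], 350 - 20 + 1, B=10_000)
    with pytest.raises(SearchFailure) as e:
        enumerate_paths(sg, 4)
    assert e.value.reason == TOO_MANY_PATHS
    assert len(enumerate_paths(sg, 40)) == 32


def test_branch_budget_exhaustion():
    k = 15
    hap1 = random_genome(400, 8)
    hap2 = list(hap1)
    for pos in (60, 120, 180, 240, 300):
        hap2[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hap1[pos]]
    g = ExactSetGraph.from_sequences([hap1, "".join(hap2)], k)
    with pytest.raises(SearchFailure) as e:
        bidi_bfs(g, hap1[20:20 + k], hap1[350:350 + k], 331, B=3)
    assert e.value.reason == TOO_MANY_BRANCHES


def test_path_to_seq():
    assert path_to_seq(["ACGT", "CGTA", "GTAC"]) == "ACGTAC"
    assert path_to_seq(["ACGT"]) == "ACGT"


def test_search_oracle_equivalence_small():
    """Bidirectional search + enumeration == exhaustive depth-limited DFS."""
    k = 21
    rng = np.random.Generator(np.random.PCG64(99))
    for seed in range(5):
        genome = random_genome(3000, 500 + seed)
        kmers = genome_kmers([genome], k)
        g = ExactSetGraph(kmers, k)
        for _ in range(20):
            i = int(rng.integers(0, len(genome) - k - 420))
            j = i + int(rng.integers(20, 400))
            start, goal = genome[i:i + k], genome[j:j + k]
            dl = j - i + 1 + int(rng.integers(0, 10))
            expect = dfs_paths(kmers, start, goal, dl)
            try:
                got = paths_of(g, start, goal, dl)
            except SearchFailure:
                got = []
            assert got == expect
            # one-sided BFS agreement
            assert got == one_sided_paths(kmers, start, goal, dl)


def test_monotone_in_depth_and_path_budget():
    g, hap1, hap2, _ = snp_bubble_fixture()
    start, goal = hap1[50:71], hap1[150:171]
    base = paths_of(g, start, goal, dl=101)
    assert paths_of(g, start, goal, dl=130)[:2] == base  # raising F keeps paths
    with pytest.raises(SearchFailure) as e:
        sg = bidi_bfs(g, start, goal, 101, B=10_000)
        enumerate_paths(sg, 1)  # lowering P only converts success to failure
    assert e.value.reason == TOO_MANY_PATHS


# ---------------------------------------------------------------------------
# consensus

def test_consensus_examples():
    assert consensus(["ACGTA"], M=None, X=98.0) == "ACGTA"
    assert consensus(["ACGTA", "ACCTA", "ACCTA"], M=1, X=0.0) == "ACCTA"
    # two 100 bp paths with 3 mismatches: identity 97% < X=98 -> disagree
    a = random_genome(100, 10)
    b = list(a)
    for pos in (10, 50, 90):
        b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[a[pos]]
    with pytest.raises(SearchFailure) as e:
        consensus([a, "".join(b)], M=None, X=98.0)
    assert e.value.reason == PATHS_DISAGREE
    assert consensus([a, "".join(b)], M=None, X=96.0)  # within tolerance


def test_consensus_mismatch_limit_counts_gap_columns():
    with pytest.raises(SearchFailure):
        consensus(["AAAATTTT", "AAAACTTTT"], M=0, X=0.0)  # one gap column
    got = consensus(["AAAATTTT", "AAAACTTTT", "AAAACTTTT"], M=1, X=0.0)
    assert got == "AAAACTTTT"  # majority keeps the insertion


def test_consensus_tie_breaks_lexicographically():
    assert consensus(["AAT", "ACT"], M=None, X=0.0) == "AAT"


def test_needleman_wunsch_validity_and_edlib_bound():
    import edlib

    from konnector.search import _pairwise_stats
    rng = np.random.Generator(np.random.PCG64(4))
    for _ in range(10):
        a = random_genome(int(rng.integers(20, 80)), int(rng.integers(1e6)))
        b = random_genome(int(rng.integers(20, 80)), int(rng.integers(1e6)))
        aa, bb = needleman_wunsch(a, b)
        assert aa.replace("-", "") == a and bb.replace("-", "") == b
        assert len(aa) == len(bb)
        # non-match columns of any global alignment bound the edit distance
        mism, cols = _pairwise_stats(a, b)
        dist = edlib.align(a, b, task="distance")["editDistance"]
        assert dist <= mism <= cols


# ---------------------------------------------------------------------------
# connect_pair

def test_connect_pair_recovers_exact_fragment():
    genome = random_genome(20_000, 55)
    cfg = SimConfig(genome_len=20_000, err_rate=0.0, coverage=4, seed=56)
    pairs = simulate_pairs(genome, cfg)
    g = ExactSetGraph(kmerize(genome, 31), 31)
    params = ConnectParams(k=31)
    for p in pairs[:40]:
        if p.frag_len > params.F:
            continue
        res = connect_pair(g, p.read1, p.read2, params)
        assert res.connected
        truth = genome[p.frag_start:p.frag_end]
        assert res.pseudo_read == truth
        # ends carry read1's 5' terminus and revcomp(read2)'s 3' terminus
        assert res.pseudo_read.startswith(p.read1[:10])
        assert res.pseudo_read.endswith(revcomp(p.read2)[-10:])


def test_connect_pair_fragment_beyond_F_fails():
    genome = random_genome(5000, 57)
    g = ExactSetGraph(kmerize(genome, 31), 31)
    r1 = genome[1000:1100]
    r2 = revcomp(genome[1700:1800])  # fragment 800 > F=525
    res = connect_pair(g, r1, r2, ConnectParams(k=31))
    assert res.status == NO_PATH


def test_connect_pair_corrects_read_error():
    genome = random_genome(6000, 58)
    g = ExactSetGraph(kmerize(genome, 31), 31)
    start = 2000
    frag = genome[start:start + 400]
    r1 = list(frag[:100])
    r1[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r1[50]]
    res = connect_pair(g, "".join(r1), revcomp(frag[-100:]), ConnectParams(k=31))
    assert res.connected
    assert res.pseudo_read == frag  # graph path overrides the error
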