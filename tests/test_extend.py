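import numpy as np

from konnector import (ConnectParams, DuplicateFilter, ExactSetGraph,
                       collapse_bubble, correct_unconnected, extend_both,
                       extend_seq, kmerize, process_pair, revcomp)
from konnector.extend import is_novel, register
from konnector.simulate import SimConfig, random_genome, simulate_pairs
from konnector.walks import FP_BRANCH_LEN

from oracles import canon

K = 21
SUB = {"A": "C", "C": "G", "G": "T", "T": "A"}


def linear_graph(genome, k=K):
    return ExactSetGraph(kmerize(genome, k), k)


def plant_spur(kmers, genome, pos, length, k=K, rng=None):
    """Attach a <=3-node false branch to the node at ``pos``; returns new set."""
    out = set(kmers)
    word = genome[pos:pos + k]
    cur = word
    added = 0
    bases = list("ACGT")
    while added < length:
        nxt = None
        for b in (rng.permutation(bases) if rng is not None else bases):
            cand = cur[1:] + str(b)
            if canon(cand) not in out and cand != genome[pos + added + 1:
                                                         pos + added + 1 + k]:
                nxt = cand
                break
        if nxt is None:
            break
        out.add(canon(nxt))
        cur = nxt
        added += 1
    return out


def test_extend_reaches_near_genome_ends():
    genome = random_genome(2000, 21)
    g = linear_graph(genome)
    seed_seq = genome[900:900 + 3 * K]
    got = extend_both(g, seed_seq, ConnectParams(k=K))
    assert got == genome  # extends to both dead ends of the linear graph


def test_extend_is_zero_when_seed_absent():
    g = linear_graph(random_genome(500, 22))
    foreign = random_genome(80, 23)
    assert extend_seq(g, foreign, "right") == foreign


def test_extend_stops_at_genuine_fork():
    # two >= 4-node arms diverging from a shared stem
    stem = random_genome(300, 24)
    arm1 = stem + random_genome(200, 25)
    arm2 = stem + random_genome(200, 26)
    g = ExactSetGraph.from_sequences([arm1, arm2], K)
    got = extend_seq(g, stem[:3 * K], "right")
    assert len(got) <= len(stem)  # never walks past the fork


def test_extend_ignores_short_spur():
    genome = random_genome(1500, 27)
    g0 = linear_graph(genome)
    seed_seq = genome[700:700 + 3 * K]
    base = extend_both(g0, seed_seq, ConnectParams(k=K))
    rng = np.random.Generator(np.random.PCG64(0))
    kmers = plant_spur(set(g0.kmers), genome, 400, 2, rng=rng)
    kmers = plant_spur(kmers, genome, 1000, 3, rng=rng)
    g1 = ExactSetGraph(kmers, K)
    assert extend_both(g1, seed_seq, ConnectParams(k=K)) == base


def test_collapse_bubble_snp_and_permanent_divergence():
    hap1 = random_genome(300, 28)
    pos = 150
    hap2 = hap1[:pos] + SUB[hap1[pos]] + hap1[pos + 1:]
    g = ExactSetGraph.from_sequences([hap1, hap2], K)
    opener = hap1[pos - K:pos]
    cont = collapse_bubble(g, opener, "right")
    assert cont == hap1[pos + 1:pos + 1 + K]  # reconvergence node past the SNP
    # extension traverses the bubble and emits one of the two haplotypes
    got = extend_seq(g, hap1[:3 * K], "right")
    assert got in (hap1, hap2)  # one haplotype, end to end
    # permanently diverging branches are not collapsed
    arm1 = hap1[:pos] + random_genome(150, 29)
    g2 = ExactSetGraph.from_sequences([hap1, arm1], K)
    assert collapse_bubble(g2, opener, "right") is None


def test_collapse_bubble_three_way_fork_is_none():
    stem = random_genome(120, 30)
    arms = [stem + random_genome(120, 31 + i) for i in range(3)]
    g = ExactSetGraph.from_sequences(arms, K)
    assert collapse_bubble(g, stem[-K:], "right") is None


def test_correct_unconnected_geometry():
    genome = random_genome(3000, 33)
    g = linear_graph(genome)
    read = genome[1000:1100]
    got = correct_unconnected(g, read)
    # k left steps + start + up to k+1 right steps -> <= 2k+2 nodes
    assert got is not None
    assert len(got) == (2 * K + 2) + K - 1
    # anchored at the rightmost solid k-mer of the read
    right_end = 1100 - K  # offset of the run's rightmost k-mer
    assert got == genome[right_end - K : right_end + 2 * K + 1]


def test_correct_unconnected_aborts_near_dead_end():
    genome = random_genome(400, 34)
    g = linear_graph(genome)
    # leftward walk cannot complete k steps: run starts too close to the 5' end
    read = genome[5:5 + K + 2]
    assert correct_unconnected(g, read) is None


def test_correct_unconnected_right_walk_stops_at_fork():
    stem = random_genome(400, 35)
    arm1 = stem + random_genome(100, 36)
    arm2 = stem + random_genome(100, 37)
    g = ExactSetGraph.from_sequences([arm1, arm2], K)
    read = stem[-120:-20]  # rightmost k-mer sits ~20 bases before the fork
    got = correct_unconnected(g, read)
    assert got is not None
    assert got in stem  # kept up to the fork, never beyond


def test_duplicate_filter_semantics():
    d = DuplicateFilter(K, 1 << 16, 3)
    seq = random_genome(120, 38)
    assert d.is_novel(seq)                     # fresh filter
    assert is_novel(d, kmerize(seq, K))
    register(d, seq)
    assert not d.is_novel(seq)                 # registered verbatim
    assert not d.is_novel(seq[10:90])          # any substring >= k
    assert not d.is_novel(revcomp(seq))        # strand-symmetric
    other = random_genome(120, 39)
    assert d.is_novel(other)                   # disjoint sequence
    # sharing all but one k-mer still counts as novel
    assert d.is_novel(seq + other[0])
    assert not d.is_novel("NNNN")              # nothing to assert


def test_process_pair_dedup_and_v1_mode():
    genome = random_genome(6000, 40)
    cfg = SimConfig(genome_len=6000, err_rate=0.0, coverage=4, seed=41)
    pairs = [p for p in simulate_pairs(genome, cfg) if p.frag_len <= 525]
    g = linear_graph(genome, 31)
    params = ConnectParams(k=31)
    d = DuplicateFilter(31, 1 << 20, 4)
    out1, res1 = process_pair(g, d, pairs[0].read1, pairs[0].read2, params)
    assert res1.connected and len(out1) == 1
    assert out1[0].provenance == "connected_extended"
    out2, res2 = process_pair(g, d, pairs[1].read1, pairs[1].read2, params)
    assert res2.connected and out2 == []  # suppressed as duplicate
    # v1.0 compatibility: one pseudo-read per connected pair, no dedup
    outs = []
    for p in pairs[:3]:
        emitted, _ = process_pair(g, None, p.read1, p.read2, params,
                                  extend_enabled=False)
        outs.extend(emitted)
    assert [o.provenance for o in outs] == ["connected"] * 3
    assert [o.seq for o in outs] == [genome[p.frag_start:p.frag_end]
                                     for p in pairs[:3]]


def test_process_pair_unconnected_reads_are_corrected_and_extended():
    genome = random_genome(6000, 42)
    g = linear_graph(genome, 31)
    params = ConnectParams(k=31)
    d = DuplicateFilter(31, 1 << 20, 4)
    r1 = genome[1000:1100]
    r2 = revcomp(genome[2400:2500])  # fragment 1500 >> F: unconnectable
    out, res = process_pair(g, d, r1, r2, params)
    assert not res.connected
    assert 1 <= len(out) <= 2
    assert all(o.provenance == "unconnected_extended" for o in out)
    # extended to the full genome, then read 2 deduplicated
    assert out[0].seq == genome
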