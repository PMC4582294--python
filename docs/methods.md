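# Methods

## Problem and model

Paired-end tag (PET) sequencing reads both ends of a DNA fragment; when the
fragment is longer than the combined read length, an unsequenced gap remains
between the mates.  With redundant coverage the gap can be reconstructed
*locally*: the k-mer spectrum of the read set defines an implicit de Bruijn
graph (nodes: k-mers; edges: k-1 base overlaps, never stored — the four
possible single-base extensions are simply queried for membership), and a
path between a k-mer of read 1 and a k-mer of read 2 spells the missing
sequence.  `konnector` implements this read-pair connection, an optional
extension of the results to the surrounding unambiguous sequence, and a
scaffold gap-closing application (`seal`) driven by the same core.

## Graph representation

K-mers are stored in a two-level (cascading) Bloom filter: level 1 holds
k-mers seen at least once, level 2 those seen at least twice.  An incoming
k-mer already present in level 1 is promoted to level 2.  After loading,
level 1 is discarded and all graph queries hit level 2 only; since a
sequencing error at low error rates almost always produces singleton
k-mers, the level-2 graph is largely error-free without any counting.

Node identity is the canonical k-mer (lexicographic minimum of the word and
its reverse complement), making the graph strand-symmetric.  Traversal
always carries the *oriented* word, so left/right are well defined even at
palindromic k-mers.

Hashing must accommodate k well beyond 32 (the gap-closing sweep uses k up
to 250), so k-mers are not packed into 64-bit integers.  Instead each word
is hashed by a fixed-multiplier polynomial over its base codes, mod 2^64;
adding the polynomial of the reverse complement makes the value
strand-symmetric without choosing an orientation.  Two independent
multipliers give two 64-bit values, finalized by splitmix64 and combined by
double hashing into the `h` bit positions.  All constants are frozen, so
filter files are bit-reproducible; a bulk (vectorized) loading path and the
scalar query path are verified against each other bit-for-bit in the tests.

Sizing defaults to 12 bits per loaded k-mer occurrence across the two
levels (6 per level, `h = round(ln2 * m/n)`, floor 1).  Because occurrences
over-count distinct k-mers at redundant coverage, the realized
false-positive rate is far below the `(1 - e^{-hn/m})^h` value this ratio
would suggest for distinct-element loads; both regimes are exercised in the
tests.  The on-disk format is a little-endian header (magic `KONBLOOM`,
version, k, level count) followed by each retained level's parameters and
raw bit array; loading verifies magic, version, k, and length, and refuses
truncated files.

## Anchors

Searches start from trusted sequence.  The solidity mask of a read marks
positions whose k-mer is in the graph; among runs of at least three solid
k-mers the run closest to the 3' (gap-facing) end is chosen and the anchor
is the 5'-most k-mer of that run — if the anchor itself is a Bloom false
positive, the search still proceeds through at least two more solid k-mers
rather than dead-ending immediately.  With no run of three, the longest run
is used (ties toward 3').  Read 2 is anchored in its own orientation (its
3' end also faces the gap in an FR library) and the anchor is mapped onto
the fragment strand by reverse complement.

## Path search and consensus

Between the two anchors a depth-limited, bidirectional, breadth-first
search is run.  *All* connecting paths up to the depth limit matter (hence
BFS rather than a shortest-path algorithm): alternate paths are either
collapsed into a consensus or cause the pair to be rejected, which is what
protects the output from arbitrary route choices through tangles.

The two frontiers strictly alternate one level at a time, forward first, at
most `ceil(depth_limit/2) + 1` levels each; a node generated by one
frontier that the other has already visited is recorded as a *common edge*
and not expanded further.  The depth limit is `F - offset1 - offset2 - k +
1` nodes, so a connecting path can never push the assembled pseudo-read
past the maximum fragment length `F`.  A branch budget `B` counts every
extra node dequeued at a fork, summed over both frontiers; exceeding it
fails the pair (`too_many_branches`).  Path enumeration is an exhaustive
depth-limited walk over the visited-node set (adjacency between member
k-mers is implied by overlap, so no further membership queries are needed);
walks may revisit nodes, the depth limit bounds them, and more than `P`
walks fails the pair (`too_many_paths`).  The tests pin this machinery to
an independent brute-force DFS over the full k-mer set.

A single path is spelled directly.  Equal-length alternates are merged by
column-wise majority (ties to the lexicographically smallest base);
unequal-length alternates go through a center-star multiple alignment
around the longest sequence (exact Needleman–Wunsch pairwise alignments,
match +1 / mismatch -1 / gap -2, deterministic trace-back).  Before
merging, every pair of alternates must show at most `M` mismatch columns
(gaps included; `M` may be unlimited) and at least `X`% identity, else the
pair fails (`paths_disagree`).  With the defaults (`P=4`, `M` unlimited,
`X=98`) an isolated SNP bubble merges cleanly while genuinely divergent
routes are rejected.

The pseudo-read is read 1's pre-anchor prefix + the connecting consensus +
the post-anchor suffix of revcomp(read 2).  The bases between the anchors
come from the graph and are therefore implicitly error-corrected.  The
flanks outside the anchors are spelled from the graph as well, by a linear
walk outward from each anchor (`correct_flanks`, on by default): when an
error splits a read's solidity mask, the chosen anchor sits downstream of
the error and the pre-anchor flank would otherwise re-introduce it
verbatim.  Where the walk meets a fork or dead end the read bases are kept
unchanged.  The gap-closing application turns this off — its "reads" are
assembly flanks, which must be embedded verbatim in a closure.

## Extension, correction and duplicate suppression

With extension enabled, a connected pseudo-read is walked outward in both
directions until a dead end or a genuine fork.  Three look-ahead rules
apply to every step:

* at a fork, branches through which no walk longer than three nodes
  exists are treated as Bloom false-positive branches and ignored.  A
  lone continuation at a chain end is real sequence, not a branch, and is
  always followed — which also lets extensions reach the true graph dead
  ends, so that the duplicate filter fully covers a linear stretch after
  its first emission.
* at a fork with exactly two surviving branches, a look-ahead of k+1 nodes
  checks whether the arms reconverge at the same depth (the signature of a
  heterozygous-SNP bubble: a single substitution yields parallel arms of k
  interior nodes).  If so the bubble is collapsed and the walk continues;
  the emitted arm is the lexicographically smaller one, deterministically.
* a visited set terminates walks on circular structures, and an optional
  per-direction length cap (`max_extension`) is available; the default is
  uncapped, i.e. extension truly runs to the next branching point or dead
  end.

Unconnected reads are first corrected: from the rightmost k-mer of the
read's longest solid run, the walk steps left exactly k linear nodes
(aborting on a fork or dead end — k steps provably exit any branch or
bubble a single recurrent read error can create, since such artifacts are
at most k nodes long), then right up to k+1 nodes, truncating early but
keeping what was built.  The result (at most 2k+2 nodes) is the
high-confidence query sequence.

Because reads on the same linear stretch all extend to the same sequence, a
separate duplicate filter (a plain Bloom filter, sized like one graph
level by default) tracks the k-mers of everything emitted.  A connected
pair queries it with the k-mers of the connecting sequence only (those are
putative non-error k-mers, so a covered locus yields a 100% hit rate); an
unconnected read queries with its corrected sequence.  Anything with at
least one novel k-mer is extended, registered (full extended sequence) and
emitted; everything else is suppressed.  Read 1 of a pair is processed
before read 2, so read 2's novelty is tested after read 1's registration.
With extension off the tool reverts to the earlier behaviour: one
pseudo-read per connected pair, no duplicate suppression.

## Gap closing (`seal`)

Maximal N-runs in each scaffold are located; up to 100 bp of N-free
sequence adjacent to each side (trimmed at sequence ends and neighbouring
gaps) become the 5' and 3' flanks.  The 5' flank plays read 1 and the
reverse complement of the 3' flank plays read 2, and connection is
attempted over a descending k sweep (default 90..40; one Bloom filter per
k, built once from the read set and reused across gaps) with the
gap-closing connection settings `B=1000, F=700, P=10`.  The first
successful k wins.  A closure must carry both flank anchor k-mers verbatim
at its ends, else it is rejected as consensus drift.  Patching replaces the
span from the start of the 5' flank to the end of the 3' flank with the
closure, so the patched scaffold contains the closure verbatim and no base
outside replaced spans changes; the report counts gaps total/closed and the
percentage to one decimal.

## Synthetic data

The simulator generates i.i.d. uniform ACGT genomes, an optional second
haplotype with i.i.d. heterozygous SNPs, and FR read pairs: fragment
lengths N(mean, sd) rounded and truncated to [2*read_len, genome length],
uniform starts, read 1 the fragment prefix and read 2 the reverse
complement of its suffix, substitution errors i.i.d. per base.  Defaults
are the synthetic benchmark conditions: 0.1% error, 50x coverage, 400 +-
50 bp inserts, 100 bp reads.  All randomness flows from one seeded PCG64
stream, and the truth table stores exact fragment coordinates so outputs
are scored by string equality, with no aligner in the loop.

The model deliberately omits indel errors (negligible at these settings for
the platform emulated, and their absence keeps truth comparison
exact-match), quality-score profiles, GC bias, optical duplicates and
adapter read-through.  Passing tests therefore demonstrate the graph and
search machinery under the stated statistical assumptions, not robustness
to platform-specific artifacts; on real data the quality trim (`-q`, hard
3' truncation at the first base below the threshold, default 15) is the
only concession to non-uniform quality.

## Problem sizes and numerical choices

The test suite and the acceptance script run, per invocation: Bloom
calibration over five (m, h, n) settings with 10^4 probes each; search
vs. brute-force-DFS agreement on random 3 kb genomes (k=21, anchor pairs up
to 500 nodes apart); connection fidelity on a 20 kb genome at 50x (about
5,000 pairs, k=31, F=525), error-free and at 0.1% error; extension
conservation on the same fixture; and a gap-closing round trip on a 100 kb
genome with 20 masked 50-300 bp windows (k sweep 90/70/50/40).  These sizes
were chosen as the smallest at which every phenomenon of interest (solid
runs, bubbles, duplicate suppression, k-sweep fallback) occurs at realistic
rates.  Connection rates for error-free data are reported over pairs whose
true fragment fits within `F`, since longer fragments are rejected by the
depth limit by design.

Determinism throughout: fixed hash constants, neighbor iteration in
A<C<G<T order, strict frontier alternation (forward first), lexicographic
tie-breaks in consensus and bubble collapse, and single-stream seeding in
the simulator.  Output is independent of the worker-count flag; pairs are
always processed in input order.

## Known limitations

* Bloom false positives can, with small probability, create spurious
  alternate paths; the consensus identity checks and the `P` budget bound
  the damage but cannot eliminate it.
* Terminal k-mers of a sequenced region that are seen only once never
  enter the level-2 graph, so the extreme ends of a contig are not
  reconstructed; a Bloom false positive hanging off a true dead end is
  followed as if it were sequence (it is indistinguishable from one
  without counts).
* Fragments longer than `F` are unconnectable by construction; their reads
  are only recovered through the unconnected-read path.
* Bubble collapse handles equal-depth (substitution) bubbles only; small
  indel bubbles stop the extension at the fork.
* The duplicate filter can (rarely) suppress a genuinely novel sequence
  when all of its query k-mers collide; the filter is sized like a graph
  level to keep that probability negligible.
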