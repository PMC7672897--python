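# Methods

This document describes the algorithms implemented in `cloverasm`, the
parameter defaults and the reasoning behind them, the simulator's scope,
and the main design decisions. Module names in parentheses refer to
`src/cloverasm/`.

## Problem setting and assumptions

Input is one or more short-read libraries (FASTA/FASTQ, optionally
gzipped, single or paired with a known insert size). The assembler
assumes substitution-dominated errors (the short-read regime), roughly
uniform coverage, and inward-facing ("fr") pairs with approximately
normal insert sizes. Indels, chimeric reads and coverage bias are not
modelled by the cleaning heuristics beyond what the generic graph
operations remove.

## Pipeline overview

1. **k-mer extraction** (`kmer_clustering.extract_kmers`). Reads are
   split at non-ACGT characters; fragments shorter than k are dropped.
   Every k-mer is stored canonically — the lexicographic minimum of the
   k-mer and its reverse complement — with occurrence counts and
   adjacency counts (consecutive k-mer pairs within a read), both used
   later for edge frequencies.

2. **Hamming clustering** (`kmer_clustering.cluster_kmers`). Two k-mers
   belong together when their Hamming distance, directly or against the
   reverse complement, is at most *p*. Finding candidate pairs uses the
   pigeonhole principle: each k-mer is cut into *p* + 1 contiguous
   substrings (balanced lengths, longer pieces first), and a pair within
   distance *p* must match exactly on at least one piece, because *p*
   mismatches cannot touch all *p* + 1 pieces. Only bucket collisions are
   verified base-by-base with early exit. Clusters are the connected
   components of the resulting graph, found by BFS in lexicographic root
   order so results are independent of hash iteration order. `p = 0`
   short-circuits to singletons.

3. **Consensus and recursive splitting** (`consensus_split`). Each
   cluster's members are oriented consistently and collapsed to a
   column-wise, occurrence-weighted majority consensus (ties broken
   A < C < G < T). Because one component can chain together k-mers from
   distinct genomic loci, a node is recursively split: scanning columns
   left to right, the first column where some minority nucleotide *x*
   satisfies occ(*x*) >= sp * occ(consensus) partitions the members by
   their nucleotide in that column. The comparison is done in exact
   rational arithmetic so the sp threshold has no floating-point edge
   cases. Splitting repeats until every node is stable. Duplicate
   consensus sequences are merged with summed counts; total occurrence
   mass is conserved throughout.

4. **de Bruijn graph** (`debruijn`). Nodes are the consensus k-mers
   (stored canonically); a bidirected edge joins two oriented nodes when
   the (k−1)-suffix of one equals the (k−1)-prefix of the other. Edge
   frequencies are the read adjacency counts projected through the
   member-to-consensus map, so they reflect how often reads actually
   crossed the junction. Maximal unbranched chains are compacted into
   unitigs; node coverage is the k-mer-count-weighted mean; cycles
   compact into a node with a self-loop.

5. **Cleaning** (`debruijn`). Four standard operations, in order:
   - *Spectral trimming*: edges with frequency < cs are removed, then
     isolated nodes with coverage < cs (no-op when cs = 0).
   - *Tip clipping*: dead-end branches shorter than 2k are removed when
     the junction offers a higher-frequency alternative (equal
     frequencies drop the lexicographically smaller sequence, for
     determinism).
   - *Bubble popping*: two single-node parallel paths (length <= 3k)
     between the same junction pair are compared by alignment identity
     (edlib); at >= 90% identity the lower-frequency path is folded into
     the survivor — its edge frequencies are added to the survivor's
     edges, and half its coverage mass to the survivor node.
   - *Erroneous connections*: an edge whose frequency is < cs **and**
     less than half the median frequency of the other edges at its
     endpoints (falling back to endpoint coverages when there are none)
     is a likely chimera and is removed.
   The graph is re-compacted after each operation that changed it.

6. **Sub-k extension** (`extension`). Cleaning can delete a junction
   entirely, leaving unitig ends that still overlap exactly but by less
   than k − 1. Free ends sharing an exact overlap are joined when the
   match is mutually unique, trying overlap lengths from k − 1 down to
   the minimum *m* (default ⌊k/2⌋ + 1 — long enough that random-sequence
   collisions are rare at typical k). Self-joins are forbidden.

7. **Read threading** (`scaffolding.thread_reads` /
   `resolve_junctions`). Reads are walked exactly through the graph;
   each read that crosses a junction votes for the (in-edge, out-edge)
   pairing it used. A junction is split into one node copy per pairing
   only when the votes form a perfect matching over all of its edges
   with every pairing supported by at least two reads — the read-coherent
   (Eulerian) resolution of collapsed repeats. Anything less leaves the
   junction intact, cutting contigs there rather than guessing.

8. **Scaffolding** (`scaffolding`). Each read is anchored to a single
   unitig by exact k-mer seeding (first and last k-mer, both
   orientations) plus a full-containment check at >= 95% identity; reads
   placing on multiple unitigs are repeat-ambiguous and dropped. Mate
   pairs anchored to different unitigs vote for an oriented link; a link
   needs support >= ss, its gap is the lower median of per-pair
   estimates (insert size minus the sequence consumed on each side), and
   conflicting links at one contig end keep only the strongest.
   Libraries are processed shortest insert first. Contigs are chained
   greedily (strongest links first) and gaps are written as
   max(gap, 1) Ns, so overlapping or touching contigs still show a
   single N junction marker. `ml` filters short output sequences.

## Parameters

| Flag | Meaning | Default | Rationale |
|------|---------|---------|-----------|
| `-k` | k-mer length | required | genome/read-length dependent |
| `-p` | clustering error allowance | 0 | p/k is the per-base error tolerated; p=1, k=40 tolerates 2.5%, matching typical short-read error rates |
| `-hp` (sp) | splitting threshold | 0.6 | a minority needs ~60% of the majority's support to be treated as a second locus rather than noise |
| `-cs` | low-frequency cutoff | 5 | below ~5 observations at 30x an edge is overwhelmingly an error artifact; use 0 for error-free data |
| `-ss` | scaffold support | 5 | five independent pairs make a spurious link improbable |
| `--min-overlap` (m) | minimum extension overlap | ⌊k/2⌋+1 | e.g. 24 at k=46 |
| `-ml` | minimum output length | 0 | reporting choice only |
| `-is` | library insert size | — | required for paired libraries |

Internal knobs with defaults tied to k: maximum tip length 2k, maximum
bubble path length 3k, bubble identity 0.9.

## Simulator (`simulate`)

`clover-sim` generates an i.i.d. random genome at a chosen GC fraction
(optionally with planted exact repeats), then inward paired reads with
normal insert sizes (clamped to [read length, genome length]), uniform
fragment starts and strands, and i.i.d. substitution errors. The pair
count is ceil(coverage x G / (2 x read length)). Not modelled: indels,
quality values (written as uniform), PCR duplicates, coverage bias.
`censor_pairs` drops every pair with a mate overlapping given intervals —
used in tests to carve unassemblable gaps while keeping gap-spanning
pairs for the scaffolder. All randomness flows through
`numpy.random.default_rng(seed)`.

## Numerical and determinism choices

- The sp comparison uses `fractions.Fraction`; all other arithmetic is
  integer except coverages and identities.
- Every iteration over dicts/sets keyed by strings or tuples is sorted
  first; node ids are assigned in deterministic creation order. Repeat
  runs are byte-identical (verified in the acceptance suite), with no
  dependence on `PYTHONHASHSEED`.
- Bubble identity uses edlib's banded alignment rather than a bespoke
  aligner.

## Validation problem sizes

The test and acceptance workloads are the package's own choices, sized to
run in seconds while leaving no behaviour untested: 20 kb genomes at 30x
for end-to-end recovery and denoising (error-free recovery yields one
contig at >= 99.9% identity; 1% errors with k=21, p=1 shrink ~108k raw
k-mers to ~28k consensus k-mers while retaining every sequenced true
k-mer), a 30.6 kb three-segment genome with two censored 300 bp gaps for
scaffolding (gap estimates within ~15 bp of truth at insert 500 ± 30),
and 200 random clustering instances (k <= 12, up to 500 k-mers,
p in {0,1,2}) checked against an all-pairs brute-force oracle.

## Known limitations

- Terminal genomic k-mers that no read samples cannot be recovered by
  any method; recovery assertions are therefore stated over *sequenced*
  true k-mers (on a 20 kb linear genome at 30x, about 10 of ~20k true
  k-mers near the ends are never sequenced).
- With error-free reads the spectral cutoff cs=5 erodes contig ends
  (edge frequencies ramp down near genome ends); error-free runs should
  use `-cs 0`.
- Gap estimates carry a small negative bias (~10 bp at insert 500)
  because pairs whose mates would touch the gap flanks are preferentially
  censored/unmapped; estimates remain well within one insert standard
  deviation.
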