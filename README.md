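# cloverasm

A clustering-oriented de novo assembler for short DNA reads.

Short-read assemblers built on de Bruijn graphs are highly sensitive to
sequencing errors: a single substitution creates up to *k* spurious k-mers
that fragment the graph. `cloverasm` attacks the problem *before* the graph
is built. All distinct k-mers are clustered by Hamming distance (at most
*p* mismatches, directly or via reverse complement), each cluster is
collapsed to an occurrence-weighted consensus k-mer, and clusters that
merged distinct genomic loci are recursively split wherever a minority
nucleotide is nearly as frequent as the consensus (threshold *sp*). The
denoised k-mer set then feeds a conventional pipeline: bidirected de Bruijn
graph, unitig compaction, graph cleaning (low-frequency edge trimming, tip
clipping, bubble popping, erroneous-connection removal), sub-k overlap
extension, read threading across junctions, and paired-end scaffolding with
insert-size gap estimates.

Finding all k-mer pairs within Hamming distance *p* is made tractable by a
pigeonhole index: each k-mer is cut into *p* + 1 contiguous substrings, and
any pair within distance *p* must agree exactly on at least one substring,
so only k-mers sharing a substring bucket are verified base-by-base.

## Quick start

Simulate a 20 kb genome with 1% substitution errors and assemble it:

```sh
clover-sim --genome-length 20000 --coverage 30 --error-rate 0.01 \
           --insert-mean 300 --seed 7 -o sim
clover -k 21 -p 1 -hp 0.6 -cs 5 -ss 5 \
       -i1 sim_1.fastq -i2 sim_2.fastq -is 300 -o out
```

which prints

```
Contigs
  Num    1
  Total  19990
  Max    19990
  N50    19990
  E-size 19990.0

Scaffolds
  Num    1
  Total  19990
  Max    19990
  N50    19990
  E-size 19990.0
```

and writes `out_contig.fasta` and `out_scaffold.fasta`.

Key flags: `-k` k-mer length, `-p` error allowance (maximum Hamming
distance for clustering; `-p 0` disables clustering), `-hp` splitting
threshold *sp*, `-cs` low-frequency edge cutoff, `-ss` scaffold support,
`-ml` minimum output length, `--min-overlap` minimum extension overlap
(default ⌊k/2⌋+1), `-is` insert sizes (one per library, comma-separated
like `-i1`/`-i2`). Run `clover --help` for the full list; a YAML file via
`--config` can supply any of them.

The same pipeline is importable: see `cloverasm.pipeline.assemble` /
`run_pipeline` and `docs/methods.md` for the algorithmic details.

## Testing

```sh
python -m pytest -q tests/
```

The suite (about 40 seconds) covers parsing, clustering against an
all-pairs brute-force oracle, consensus/splitting worked examples, graph
construction against a textbook de Bruijn construction, cleaning, extension,
scaffolding, statistics, the simulator, and the CLI, plus an acceptance
module with one test per headline criterion.

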