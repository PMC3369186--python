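# sparseasm

A de novo genome assembler built on a **sparse k-mer graph**: instead of
storing every observed k-mer as a node (as a de Bruijn graph does), the
graph keeps roughly one of every *g* k-mers and connects neighbouring
nodes with short link labels of at most *g* bases.  This shrinks the graph
about *g*-fold while retaining enough information to assemble contigs of
comparable quality, so moderate genomes fit in laptop-class memory.

The package contains:

| module | what it does |
| --- | --- |
| `sparseasm.seqio` | FASTA/FASTQ I/O, 2-bit k-mer codes, reverse complement, canonical form |
| `sparseasm.sparse_graph` | two-round sparse graph construction (node selection, link building) and the closed-form memory model |
| `sparseasm.cleaning` | low-coverage removal, tip clipping, bubble popping (bp-ordered Dijkstra-like BFS) |
| `sparseasm.assembly` | unitig traversal to contigs and the end-to-end pipeline |
| `sparseasm.simulate` | seeded random genomes and uniform short-read simulation with substitution errors |
| `sparseasm.evaluate` | N50/NG50 metrics, exact-match misjoin validation, node-count experiments |

## Command line

```sh
# simulate 30x 100 bp reads with 0.5% substitution errors
sparseasm simulate --random-genome 100000 --coverage 30 --read-len 100 \
    --error-rate 0.005 --seed 1 --out reads.fq --ref-out ref.fa

# assemble (k-mer size 31, skip size 15)
sparseasm assemble --reads reads.fq --k 31 --g 15 --out contigs.fa \
    [--min-node-cov 2] [--min-link-cov 1] [--max-tip-bp N] \
    [--max-bubble-bp N] [--min-contig 100] [--graph-dump graph.tsv]

# metrics (+ misjoin validation against the known reference)
sparseasm stats --contigs contigs.fa --ref ref.fa --out report.tsv

# node-count vs g experiment
sparseasm kmer-experiment --ref ref.fa --k 31 --g 1,8,16 --coverage 30 \
    --read-len 100 --error-rate 0 --seed 1
```

## Library example

```python
import sparseasm as sa

genome = sa.random_genome(100_000, seed=42)
reads = sa.simulate_reads(genome, sa.SimulationConfig(coverage=30, read_len=100, seed=7))
contigs, report = sa.assemble(reads, sa.GraphParams(k=31, g=15, node_min_cov=0, link_min_cov=0))
misjoins, corrected, coverage = sa.validate_contigs(contigs, genome)
```

## Algorithm notes

* **Node selection (round 1).**  Scanning each read from the last selected
  position *a*, the *g* following k-mer positions are queried for an
  existing node; the nearest match re-anchors the scan, otherwise a new
  node is created at *a + g* (at the first usable k-mer when a read or
  post-`N` segment starts fresh).  Consecutive selections within a read are
  therefore never more than *g* apart, which is what guarantees any two
  reads overlapping by at least *k + g* bases share a stored node.
* **Link building (round 2).**  Reads are re-scanned; every position whose
  canonical k-mer is a node counts as a match, node coverage is recounted
  from the matches, and each consecutive pair of matches at distance 1..g
  becomes a link labelled with the intervening bases (stored mirrored on
  both endpoints).  Construction is read-order dependent by design; tests
  fix read order and seeds.
* **Cleaning.**  Low-coverage nodes/links are dropped, then tips (short
  dead-end stubs attached alongside a competing entry into a junction) are
  clipped and bubbles popped (the parallel branch with lower mean node
  coverage loses) until a fixpoint.
* **Traversal.**  Unitig rule: a walk extends only while the current side
  has exactly one link and the entered side of the destination has exactly
  one link; traversal seeds are visited in ascending canonical-code order,
  making output deterministic.
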