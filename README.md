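# contigmend

Post-processor for long-read metagenomic assemblies. Given assembled
contigs and the original (adapter-free) long reads, `contigmend` first
**breaks** contigs at statistically confirmed mis-assembly points —
chimeric palindromes, repeat boundaries confirmed by coverage shifts —
and then **merges** contigs back using string-graph connectivity,
spanning reads and abundance evidence.

## How it works

**Break stage**
1. *Palindromes*: contigs that are the concatenation of a wrapping pair
   (the footprint of adapter-skipped chimeric reads) are split at the
   wrapping boundary; redundant reverse-complement pieces are dropped.
2. *Repeats*: long approximate maximal repeats (both strands, within and
   across contigs) are found by self/cross alignment. Contigs are cut at
   repeat endpoints into a fully contracted, strand-doubled segment
   graph; a minimum *sufficient breaking set* of junctions is chosen so
   the broken contigs are consistent with every feasible ground-truth
   trail partition (per weakly connected component, exhaustively below a
   size limit, a feasible fallback above it).
3. *Coverage*: each candidate junction is confirmed with an exact
   conditional test of equal Poisson read-start rates (conditioning on
   the sum makes the left count binomial under H0), applied iteratively:
   non-rejected junctions are merged away and counts aggregated until a
   fixpoint.

**Merge stage**
1. A contig-read string graph is built from reads near contig ends; it
   condenses to a contig overlay graph (nodes weighted by coverage
   depth, edges backed by read paths).
2. Graph surgery: transitive reduction and guarded edge contraction.
3. Extension candidates (contractable pairs, repeat stars, bipartite
   competing groups) are resolved into a bipartite matching by the
   spanning-read / coverage heuristic, or optionally by a
   classification-EM confidence score over read assignments and
   abundances; matched contigs are concatenated through their repeat
   node with exact end overlaps collapsed.

The aligner is pluggable: an internal exact-k-mer seed-and-extend
aligner is the default, and a parser for MUMmer `show-coords -r -c -l -T`
output lets an external aligner substitute. Everything downstream
consumes only the `Alignment` type.

## CLI

```sh
# generate a synthetic community (genomes, reads, swapped contigs, truth)
contigmend simulate --genome-len 200000 --repeat-len 12000 \
    --coverages 20,50 --seed 1 --prefix sim

# break, merge, or both
contigmend break sim.contigs.fa sim.reads.fa -o broken.fa
contigmend merge broken.fa sim.reads.fa -o merged.fa
contigmend run   sim.contigs.fa sim.reads.fa -o final.fa

# micro-benchmarks (break-graph optima, segmentation recall/precision,
# abundance-resolved merger fixture)
contigmend benchmark --seed 1 --rounds 100
```

All thresholds live in a flat YAML config (`-c config.yaml`) with
CLI-flag overrides named after the keys (`--alpha`, `--min-repeat-len`,
`--end-window`, ...). Unknown keys are rejected. Reports are
tab-separated with the resolved config embedded as comments. Exit code
is 0 on success, 2 on input error.

## Layout

```
src/contigmend/
  core_io.py          sequence records, FASTA/FASTQ, internal aligner,
                      show-coords adapter
  signal_detector.py  palindromes, repeat endpoints, coverage profile
  breaker.py          chimera fixing, break graph + sufficient breaking
                      set solver, conditional Poisson tests
  merger_graph.py     contig-read string graph, contig graph, surgery,
                      extension candidates
  contig_extender.py  matching heuristic, classification EM, merging
  synthetic.py        community/read simulators, Markov-Poisson track,
                      truth-based evaluator
  pipeline.py         stage orchestration
  cli.py, config.py   command line and configuration
```
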