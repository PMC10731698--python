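# peakforge

Reference-free ChIP-seq peak calling by de Bruijn graph partial assembly.

## The problem

ChIP-seq (and SELEX-seq, SMiLE-seq, …) experiments capture the DNA loci
bound by a transcription factor. The standard analysis maps reads to a
reference genome and then calls peaks — but a reference may be unavailable
(unsequenced organisms, metagenomic samples, aberrant genomes) or may bias
the result. `peakforge` reconstructs the bound sequences and their
enrichment **directly from the reads**, with no reference at all.

It is aimed at anyone analysing pulldown-style sequencing of organisms
without a good reference, and at methods researchers studying binding-site
context beyond the core motif.

## The method

Given treatment and control replicates and a k-mer size *k*:

1. **k-mer counting** — slide a window of size *k* over every read, count
   occurrences per replicate; sum treatment replicates and correct against
   control by depth-scaled subtraction,
   `corrected(m) = max(0, t(m) − round(s·c(m)))` with `s = T/C` the ratio of
   total k-mer instances. k-mers below an abundance threshold (absolute, or
   the *p*-th percentile of the corrected counts with singletons excluded)
   are set aside.
2. **Graph preparation** — build a node-centric de Bruijn graph: vertices
   are retained k-mers, with an edge u→v iff they overlap by k−1 **and**
   their (k+1)-base contraction was observed in the reads. Non-branching
   paths are compacted into unitigs; the graph is split into weakly
   connected components; short, highly similar parallel paths (sequencing
   error "bubbles") are merged Tour-Bus-style into the dominant arm.
3. **Partial assembly** — each component becomes a DAG (deterministic DFS
   back-edge cutting). Repeatedly: find the longest path; find its
   *bottleneck* (the vertex with the lowest per-k-mer abundance A, an upper
   bound on the abundance of all paths through it); enumerate the longest
   paths through the bottleneck; split A over at most A of them as even
   positive integers; emit those sequences, subtract their abundance from
   every k-mer used, and remove the bottleneck. Terminates when the
   component is consumed.
4. **Merging** — assembled sequences contained verbatim in a longer one are
   absorbed into it, producing *chiptigs*: sequences with a per-position
   abundance profile. The set-aside low-abundance k-mers are aligned back
   (seed-and-extend, word size 10, E ≤ 1e-3, identity ≥ 0.95) and added to
   the profiles.
5. **Peak calling** — for every chiptig longer than 1.25·k, per-replicate
   r×l abundance matrices are rebuilt (shared k-mers divided proportionally
   to the reconstructed profile); the mean treatment signal is segmented by
   a Gaussian HMM (3 states, short-run smoothing); each segment is tested
   per treatment replicate against pooled control by a one-sided
   Mann-Whitney U test with Bonferroni correction; peaks must replicate
   across all treatment replicates within a small edit-distance tolerance.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 20 kb genome with one 200 bp binding site at 20× enrichment
(50 bp reads, 0.5% substitution errors, two replicates per condition), then
run the pipeline at k = 31 with an absolute abundance threshold of 24
(twice the expected summed background k-mer coverage):

```sh
peakforge simulate --seed 7 -o sim
peakforge run \
  --treatment sim/treatment_1.fastq,sim/treatment_2.fastq \
  --control   sim/control_1.fastq,sim/control_2.fastq \
  -k 31 --abundance-threshold 24 -o out
```

which prints

```
threshold: 24
components: 1
chiptigs: 1
peaks: 4
output written to out
```

One weakly connected component survives control correction — the implanted
site — and is assembled into a single chiptig. The GHMM cuts it into four
segments, all significantly enriched:

```
$ head -3 out/peaks.tsv
chiptig_id  start  end  p_raw        p_bonferroni  n_replicates
chiptig_1   0      16   9.04718e-09  7.23775e-08   2
chiptig_1   16     151  2.82747e-61  2.26198e-60   2
```

Every peak sequence is an exact substring of the implanted site
(`sim/truth.bed` records it at positions 15900–16100). Outputs are plain
FASTA plus TSV sidecars (`chiptigs.fasta`, `chiptig_profiles.tsv`,
`peaks.fasta`, `peaks.tsv`); all intervals are 0-based half-open.

`peakforge assemble-only` runs steps 1–4 without peak calling;
`peakforge simulate --help` lists the generator's knobs.

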