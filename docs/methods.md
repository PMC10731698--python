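# Methods

This note documents the model behind `peakforge`, the defaults that matter,
and the choices made where the design was genuinely open.

## Counting and control correction

k-mers are counted per replicate with a sliding window; windows containing a
base outside A/C/G/T are skipped. Strands are **not** canonicalized: a k-mer
and its reverse complement are different sequences throughout, because the
downstream assembly reconstructs oriented sequences. Alongside the k-mer
counts, each replicate records the set of observed (k+1)-mers; these are the
only admissible evidence for graph edges.

The correction against control is depth-scaled subtraction:
`corrected(m) = max(0, t(m) − round(s·c(m)))`, `s = T/C` with T, C the total
k-mer instance counts of the summed treatment and control tables. This is
the simplest correction that (a) removes background mass proportionally to
sequencing depth and (b) is monotone in the control count of the corrected
k-mer. Correction is applied to the **summed** treatment counts, not per
replicate; per-replicate counts are kept untouched for peak calling. Note
that raising one k-mer's control count lowers `s` and therefore *weakens*
the correction of all other k-mers — only per-k-mer monotonicity holds.

Thresholding: in percentile mode the threshold is
`ceil(percentile_linear(counts ≥ 2, p))`; k-mers with a single corrected
occurrence are treated as sequencing errors and never enter the
distribution. Comparison is `count ≥ threshold`. Low-abundance k-mers are
not discarded — they are set aside and later mapped back onto the chiptigs.

## Graph

The graph is node-centric: an edge u→v requires both the k−1 overlap and
that the contraction (k+1)-mer was actually read. Building the graph from
already-thresholded k-mers makes the "unitigs may split at the abundance
cutoff" behaviour automatic. Unitig compaction merges maximal non-branching
paths and concatenates their per-k-mer abundance lists; isolated cycles are
collapsed to a single self-looped vertex starting from the lexicographically
smallest sequence, which keeps the operation deterministic and idempotent.

Bubble removal targets substitution errors: two vertex-disjoint directed
paths sharing endpoints whose **interior arms** both reconstruct to at most
`2k` bases and are ≥ 0.9 identical (edit-distance identity). The interior of
a single-substitution bubble is exactly 2k−1 bases, so the default span
covers it while staying local; measuring the span or identity over the full
paths would make the gate depend on the (arbitrarily long) flanking unitigs,
which is why the interior convention was chosen. The lower-abundance arm is
merged position-wise into the survivor (remainder onto the survivor's last
slot), so total abundance mass is conserved exactly. Because deleting arm
vertices can cut connectivity, components are deconstructed again after
bubble removal.

## Partial assembly

Cycle breaking: self-loops are always cut; a depth-first search from the
zero-in-degree vertices (falling back to the vertex of maximum total
abundance) removes every back edge it meets. Root and neighbour order are
sorted by vertex sequence, so the cut set is reproducible.

"Longest" means **bases** of the reconstructed sequence, not vertex count;
ties are broken by larger total path abundance, then by lexicographically
smallest sequence. The bottleneck of a unitig path is the vertex minimizing
the **minimum** over its constituent k-mer abundances — under this
convention the bottleneck abundance A genuinely upper-bounds the total
abundance of all paths through the vertex. Path enumeration through the
bottleneck combines all optimal-length prefixes and suffixes found by
forward/backward dynamic programming over the topological order, ranked by
total abundance then sequence; enumeration is capped at `max(A, 64)` paths
since at most A can receive abundance anyway.

A is divided over `min(A, #paths)` paths as evenly as possible in positive
integers, larger shares to earlier-ranked paths. One guard is added on top
of the even split: a path's share is capped by the smallest abundance
currently available along it. Enumerated paths can share vertices outside
the bottleneck, and without the cap a later path could subtract abundance a
shared k-mer no longer has — the cap is what makes "no k-mer's emitted mass
ever exceeds its initial abundance" an invariant rather than a hope.
Consumed k-mers at zero are deleted and their unitigs re-split around the
holes; the bottleneck vertex is removed outright, which guarantees progress
(at least one vertex disappears per iteration).

## Merging and low-abundance mapping

Within a component, assembled sequences are processed longest-first; an
exact substring of an already-kept survivor adds its path abundance over the
**leftmost occurrence in the first matching survivor** (deterministic; the
alternative of crediting every occurrence would inflate mass). Survivor
profiles start flat at the path abundance, so merging conserves
`abundance × length` exactly.

Set-aside k-mers are mapped back by seed-and-extend: exact seeds of 10
bases, ungapped extension over the full k-mer span, +1/−2 scoring, E-value
`m·n·2^(−bits)` with Karlin-Altschul bits `(1.33·S − ln 0.62)/ln 2` over the
chiptig database, acceptance at identity ≥ 0.95 and E ≤ 1e-3, best hit only
(highest identity, then longest alignment, then first chiptig). Gapped
alignment is deliberately out of scope — the error model this pipeline
corrects for is substitutions.

## Peak calling

Per-replicate abundance rows assign position j the replicate count of the
k-mer starting at j (the trailing k−1 positions inherit the last k-mer's
value). A k-mer occurring at several chiptig positions has its count divided
proportionally to the reconstructed profile values at those occurrences,
rounded by largest remainder so the replicate count is conserved exactly.

Segmentation runs on the **mean across treatment replicates** with a
3-state Gaussian HMM (diagonal covariance, EM with ≤ 10 seeded restarts,
best log-likelihood kept, Viterbi decoding). Three states capture the
background / flank-ramp / plateau structure of enriched loci; constant
signals short-circuit to a single segment. State runs of ≤ 5 bp flanked by
runs of one common state of ≥ 10 bp are rewritten to the flanking state,
iterated to a fixpoint.

Every segment of length ≥ 2 is tested per treatment replicate against the
**pooled** control rows (one-sided Mann-Whitney U, treatment greater,
normal approximation with tie correction; fully tied data returns p = 1).
Pooling the controls was chosen over replicate pairing because the test
needs no pairing assumption and pooling maximizes the control sample. The
Bonferroni family is (segments tested) × (treatment replicates) within one
run. With several treatment replicates, only peaks recovered in every
replicate within edit distance `max(4, ceil(0.05·length))` are reported,
with the first replicate's interval. No Poisson assumption is made anywhere
— the assembly process distorts count distributions, which is exactly why a
rank test is used.

## Synthetic experiments

The generator emulates: an i.i.d. uniform background genome, non-overlapping
implanted sites, uniform control coverage, treatment = the same uniform
background layer plus `round((fold−1)·depth·site_length/read_length)` extra
reads per site drawn uniformly from **within** the site (so mean site
coverage is `fold × depth` and every enriched read is a site substring),
and i.i.d. per-base substitution errors. Defaults: 20 kb genome, one 200 bp
site, fold 20, 50 bp reads, depth 15, error rate 0.5%, two replicates,
single strand. It does not model fragment-size distributions, read pairing,
PCR duplicates, quality scores, indels or mappability structure — so
passing tests demonstrate the algorithmic pipeline (counting → graph →
assembly → testing) is correct and specific under clean enrichment, not
that real-library artefacts are handled.

Problem sizes in the test suite and the acceptance script (20 kb genome,
~26k reads per run, 20 null repetitions) were chosen as the smallest
configuration where background coverage statistics are stable; the
abundance threshold used there, 24, is twice the expected summed background
k-mer coverage `2·n_reps·depth·(read_length−k+1)/read_length`, a ~5σ cut
against Poisson background fluctuations.

## Known limitations

- Highly repetitive loci can be misassembled or misread as peaks, as with
  any reference-free approach.
- Control libraries whose k-mer counts rival the treatment's suppress
  reconstruction (few retained k-mers survive correction); detectable by a
  very low chiptig count.
- The DAG conversion is a heuristic reconstruction: cutting DFS back edges
  of minimum-order is deterministic but not guaranteed to preserve the
  longest true path through a cyclic repeat.
- Peak p-values are conditioned on the assembly; they quantify enrichment
  of the reconstructed segment, not genomic FDR.
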