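# Methods

## Problem and model

Deep RNA-seq of field-grown plant tissue that has not been surface
sterilised captures transcripts from the host plant *and* from its
phyllosphere community (fungal endophytes and epiphytes, lichen algae).
After joint de novo assembly, the two populations can be separated
without reference genomes because they differ systematically in three
statistics:

* **GC content** — conifer host transcripts centre near 44.5% GC, fungal
  transcripts near 53%;
* **transcript length** — the host assembly is far more contiguous (its
  N50 is several-fold larger), since host reads dominate coverage;
* **expression breadth** — host genes are expressed in most sequenced
  samples, while each symbiont is physically present on only one or two
  samples, so its transcripts appear sample-specific.

`phyllopart` implements the partitioning statistics, the taxonomic
binning rules, the fungal-enrichment filters and the homolog clustering
as composable library functions, and a generator that synthesises
dual-population data with ground truth so every stage is testable
end-to-end without the original multi-hundred-gigabyte read set.

## Statistics

**GC percent** is `(#G + #C) / length * 100`, rounded half-even to two
decimals in decimal arithmetic (platform-independent). Ambiguity codes
count toward the length but not the GC tally. A read *pair's* GC is the
GC of the concatenated mates, which weights mates by length; the choice
of a joint rather than per-mate statistic is a convention, flagged as
such.

**N50** is the largest length L such that sequences of length >= L hold
at least half the assembled bases (sort descending, accumulate to half
the total).

**Expression chain.** Counts are normalised to FPKM with each sample's
column total as the library size (read alignment is out of scope; users
with externally quantified FPKM construct the matrix in the `fpkm`
state directly and skip the op). FPKM < 1 is floored to 0 on the log2
scale, log2 is applied at >= 1, transcripts that are zero everywhere are
removed, and tau is computed on the floored log2 values:

    tau_i = 1/(n-1) * sum_j (1 - a_ij / max_j a_ij)

tau is 1 for single-sample expression, 0 for uniform expression, and
0.8 when every non-maximal sample sits at 20% of the maximum. Whether
the flooring feeds tau directly or tau uses raw FPKM is ambiguous in
the original description; this package fixes the chain
counts -> fpkm -> floor_log2 -> tau and enforces it with a state
machine on `ExpressionMatrix`, so the choice is explicit and auditable.
tau's `n` is the number of matrix columns — samples stand in for
tissues.

Host/fungal tau distributions are compared with Welch's unequal-variance
t-test (hand-computed Welch–Satterthwaite statistic and df; scipy
supplies only the t distribution). PCA treats samples as observations
in transcript space, mean-centred, unscaled by default (scaling is a
flag).

## Taxonomic assignment

Protein hits (BLAST outfmt-6-like TSV plus a taxon column) are filtered
at e-value < 1e-3 (strict, parameterised) and ranked per transcript by
ascending e-value, then descending bitscore, then subject id — a total
order, so assignment is deterministic. The top hit's taxon label maps
to a kingdom bucket through a plain dictionary (no live taxonomy
service); unknown labels map to `other`.

A transcript with no passing protein hit but a valid host-genome
alignment is reclassified as host. Validity requires three independent
thresholds: reliable-alignment fraction (support) >= 0.99, transcript
coverage > 0.80 and identity > 0.90. The support clause exists because
the source phrasing of the rule is grammatically ambiguous; keeping the
three thresholds separate lets either reading be configured.

## Fungal enrichment

**Read-pair GC filter.** Pairs with joint GC >= 46% (inclusive — "or
higher") are kept; mate pairing is preserved and desynchronised inputs
fail loudly with the offending read id.

**Cross-sample exact-identity filter.** Host genes are expressed in
many samples, so after per-sample reassembly their transcripts recur as
long exact repeats across assemblies. A transcript is removed when
transcripts from >= 5 samples (its own included, configurable) share a
perfect >= 100-nt stretch with it. Two sequences share an exact >= k-nt
stretch iff they share a k-mer, so a canonical (strand-symmetric) k-mer
index implements the rule losslessly. "100% identical" is taken
literally: Ns never match anything, including other Ns. Transcripts
shorter than k cannot match and are always retained.

## Homolog clustering

All-vs-all local alignment (match +1, mismatch -1, gap open -5, gap
extend -2; both strands; Biopython's PairwiseAligner) yields candidate
pairs. The gap penalties are deliberately steeper than the mismatch
cost: with cheap gaps, the optimal local alignment between two
*unrelated* ~600-nt sequences can chain short chance matches through
gaps into a >= 200-column span whose column identity exceeds 52%
(observed for roughly 0.5% of random pairs), which would fuse unrelated
families; with open -5 / extend -2 no such chance match was observed in
400 random pairs while every true pair at the hardest supported family
identity (0.85 per branch, ~0.72 pairwise) was still detected. Because
optimal co-alignments can be padded with zero-scoring ends, spans and
identities are measured on the shortest window attaining the optimal
score (the standard Smith–Waterman endpoint convention).

A pair is accepted at span >= 200 columns and identity (matches over
aligned columns, gaps included) > 0.52 — identity is overlap-local, as
the pairing of an overlap-length with a similarity requirement implies.
Clustering is single linkage at distance 1 - identity cut at the edge
threshold, which makes the clusters exactly the connected components
of the match graph and removes any free cut-height parameter;
implemented with union-find and cross-checked against an independent
graph-components oracle. Clusters keep >= 4 members by default, are
represented by their longest member (ties: smallest id), and clusters
whose representative is taxonomically plant (host or other
Viridiplantae — green algae are GC-similar to fungi, hence the explicit
removal) are dropped. Pooled cluster expression is the column-wise sum
of member rows, so paralogs and cross-sample orthologs are quantified
jointly.

## Synthetic data generator

The generator emulates the statistical contrasts the analysis exploits,
with ground truth for every emitted sequence:

| parameter | default | rationale |
| --- | --- | --- |
| host / symbiont GC mean (sd) | 44.5 (3.0) / 53.1 (3.0) % | the two population modes the partition rests on |
| host / symbiont length log-mean (log-sd) | 7.5 (0.45) / 6.1 (0.45) | log-normal lengths, medians ~1800 / ~450 nt, reproducing a several-fold N50 contrast |
| samples | 22 | the number of libraries the breadth statistics assume |
| host / symbiont breadth | 0.90 / 0.05 | host in ~20 of 22 samples; 0.05*22 = 1.1 -> symbiont in 1–2 samples (stochastic rounding, floor one sample) |
| counts | NB, dispersion 0.3 | standard bulk RNA-seq overdispersion; per-transcript base mean log-normal(4, 1) |
| family model | star phylogeny, per-site substitution at 1 - identity | clustering uses identity only, so no tree structure is assumed; expected pairwise identity is identity² + (1-identity)²/3 |

Sequences are i.i.d. per-base with P(G)=P(C)=gc/2 — the simplest model
matching a mean-GC target. Read pairs sample fragments uniformly over
start positions; mate 2 is the reverse complement of the fragment's far
end, so pair GC is an unbiased estimate of fragment GC. The spike
utility copies one exact segment into one transcript in each of n
samples, planting truth for the exact-identity filter at its
boundaries (5 samples/100 nt removed; 4 samples or 99 nt retained).

Companion generators emit protein-hit and genome-alignment tables
consistent with the truth labels (hit rate 0.99; host transcripts get
valid genome alignments; 10% of symbiont transcripts get spurious
sub-threshold ones), so the taxonomy stage can be exercised including
its rescue and failure paths.

All randomness derives from one root seed: each generator uses
`SeedSequence(entropy=seed, spawn_key=(stream_index,))` with a fixed
stream index, so regenerating one artifact never perturbs the others,
and identical configurations are byte-identical on disk.

**What the generator does not emulate:** sequencing error, splicing
isoforms, chimeric assembly, rRNA/poly-A artifacts, strand-specific
libraries, phylogenetic structure within families, or the covariance
of expression between related genes. Passing tests therefore show the
*rules* are implemented correctly and recover planted structure; they
do not show the thresholds are optimal for any particular real
dataset.

## Numerical and design choices

* GC rounding is half-even in `decimal` arithmetic — binary-float
  `round()` drifts on exact halves.
* tau on an all-zero profile is undefined and raises; `drop_all_zero`
  must run first (mirrored by the matrix state machine).
* Welch on two zero-variance samples raises unless the means are equal
  (t = 0, p = 1 by continuity).
* Cluster ids are assigned by each cluster's smallest member id;
  representatives break length ties lexicographically — everything
  downstream of clustering is permutation-invariant.
* Pipeline reports contain no timestamps and are serialised with
  sorted keys, so identical inputs give byte-identical `report.json`.
* Test and acceptance problem sizes (e.g. 2,000 + 2,000 transcripts,
  10 families of 6 at ~600 nt) are chosen so the full suite runs in
  about a minute on one CPU while keeping Monte-Carlo margins wide
  (e.g. the GC-recovery check at n = 2,000 has a ~7-sigma margin).

## Known limitations

* The all-vs-all aligner is O(n² L²); it is meant for the
  post-filter scale (hundreds to a few thousand representatives), not
  raw assemblies.
* FPKM uses within-matrix column totals as library sizes; if many
  reads map outside the quantified set, supply externally computed
  FPKM instead.
* The k-mer identity filter holds its index in memory (~L bytes per
  transcript position); billion-read scale would need a disk-backed
  index, which is out of scope.
* Kingdom mapping is a static dictionary; finer-grained taxonomy
  (classes, lowest common ancestors) is out of scope.
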