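# Methods

This note documents the models and procedures implemented in lgatlas, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical and design decisions
taken where more than one defensible option existed.

## Lineage model and Abouheif proximity

The lineage tree is rooted, topology-only (branch lengths in the input are
silently dropped), with unique leaf labels — the RNA-seq samples — and at
least two children per internal node. Unifurcations are collapsed at parse
time: a single-child node would contribute a direct-descendant count of one
to every path product, a multiplicative no-op, so collapsing changes nothing
while keeping the invariant simple.

The proximity between tips *i* and *j* is `1 / Π dd(v)` over the internal
nodes *v* on the connecting path (inclusive of the most recent common
ancestor), `dd(v)` being the number of direct descendants. Two variants are
exposed:

* `"Abouheif"` (default): zero diagonal, rows divided by their sums — the
  matrix the LgPCA uses;
* `"oriAbouheif"`: the original form whose diagonal absorbs the remainder so
  raw rows sum to one.

For a star tree the symmetrized default reduces to `(J − I)/(n − 1)`, the
uniform weighting; this is also the bridge to standard PCA used as an oracle
in the tests.

## Lineage-guided PCA

With `X` the column-centered samples × genes matrix (scaled to unit gene
variance by default) and `W_s = (W + Wᵀ)/2`, the method diagonalizes
`H = (1/n) Xᵀ W_s X`. Implementation notes:

* **Duality.** `H` is genes × genes (easily 20,000²), but its non-null
  eigenvectors live in the row space of `X`. With the thin SVD `X = U S Vᵀ`,
  eigenvectors are `u = V a` where `a` diagonalizes the small symmetric
  matrix `(1/n) S (Uᵀ W_s U) S`. This is an optimization with a hard
  contract: it must (and does, to ~1e-15 relative) match the direct
  eigendecomposition on small instances.
* **Scaling.** Gene-wise unit-variance scaling is on by default: quantile-
  normalized counts span orders of magnitude, and without scaling a handful
  of very abundant genes dominate every axis. A flag disables it; constant
  genes cannot be scaled and are zeroed with a warning.
* **Ordering and retention.** Axes are sorted by signed eigenvalue,
  descending, so positive (global) axes come first. An axis is retained when
  `|λ| > 1e-9 · max|λ|`; for generic full-rank data with *n* samples this
  leaves exactly *n − 1* axes (31 for the 32-sample default atlas).
* **Identities.** `λ_k = var(y_k)·I(y_k)` with `var(y) = (1/n)Σy²` and
  `I(y) = yᵀW_s y / yᵀy` holds algebraically and is asserted to 1e-10
  relative in the tests. Axis signs are arbitrary; all comparisons in tests
  use absolute cosines.
* **Extreme genes.** The k most positive / most negative loadings per axis
  (default k = 1000) with a deterministic lexicographic tie-break on gene id.
* **Gene-set tests.** Two-sided Wilcoxon rank-sum (Mann–Whitney) of in-set
  loadings against all remaining genes, with rank-biserial effect size and a
  high/low pole direction. Sets of ≤ 10 genes are skipped (strict
  inequality), mirroring the usual minimum-annotation rule. Traversal of an
  ontology graph with elimination is out of scope; the test takes flat gene
  sets.

## Expression processing

* **Quantile normalization** uses the rank-reference construction: the
  reference for rank *r* is the mean across samples of each sample's *r*-th
  order statistic; ties within a column receive the mean of the reference
  values their tied span covers (the common implementation default — the
  alternative, arbitrary tie ordering, makes results depend on input order).
  Consequence worth noting: the "all columns share one multiset" and
  idempotence properties hold exactly on tie-free columns; tied entries carry
  averaged values instead. Column sums are equalized in every case.
* **Tau** is computed on per-tissue means of normalized counts (replicate
  columns averaged first), on the linear scale by default; a flag applies
  log2(x+1) first. τ is undefined for genes with all-zero means — these are
  reported missing (NaN), not forced to 0 or 1.
* **Prefilter** drops caller-listed genes (e.g. Y-linked genes and *XIST*
  ahead of NMF — supplied as a list to keep the operation annotation-free)
  and genes with fewer than 100 reads in total; a gene with exactly 100
  survives.

## NMF metagenes

Brunet's multiplicative KL updates, initial factors U(0, max(V)/r) under a
seeded generator. The KL divergence is recorded every iteration and is
non-increasing by construction (asserted within 1e-9 in tests). Stopping:
`max_iter` (default 2000) or an unchanged sample-connectivity matrix over 4
consecutive checks spaced 10 iterations apart; the stall stop can be disabled
to drive the objective to machine precision on exactly factorizable input.

Rank selection runs many seeded restarts per candidate rank (the study
condition is 50 runs over ranks 11–18; synthetic block experiments use the
same machinery at smaller ranks), assigns each sample to its argmax metagene,
averages the run connectivities into a consensus matrix, and scores each rank
by the cophenetic correlation of the average-linkage dendrogram of
`1 − consensus`. The maximal coefficient wins; ties break toward the smaller
rank. A flat consensus (zero distance variance) is degenerate: all-zero
distances score 1, otherwise NaN, and a winning coefficient that is NaN or
below 0.9 flags the selection unstable. A caveat observed on very clean
block data: a too-small rank can also be perfectly reproducible (every
restart merges the same pair of blocks), in which case the tie-break, not the
coefficient, decides — rank selection should always be read together with
the per-rank curve the code returns.

Metagene gene sets: gene *g* joins metagene *k* iff its row-normalized basis
weight exceeds 0.8 (strict). Any threshold above 0.5 guarantees disjoint
sets; zero basis rows stay unassigned. External samples are scored as the
mean log2(x+1) expression of each set, z-scored across metagenes within each
sample — a declared, simple enrichment statistic.

## Transcript discovery

Coordinates are 0-based half-open internally; GTF is 1-based inclusive and
converted only at the I/O boundary. Class codes are applied in the fixed
priority order j > e > p > o > x > i > u:

* **j** — any intron exactly matching a reference intron, same strand;
* **e** — unspliced, contained in a same-strand reference transcript span and
  overlapping both an exon and an intron of it (pre-mRNA fragment);
* **p** — same strand, starting downstream of a reference annotation end with
  a gap of at most 2,000 bp (run-on); the gap is measured between the
  annotation end and the transcript start, so a 2,000 bp gap is discarded and
  2,001 bp is not;
* **o / x** — exonic overlap on the same / opposite strand;
* **i** — wholly inside a reference intron (either strand);
* **u** — none of the above. Unknown chromosomes classify as u with a
  warning.

j, e and p are discarded. Positional classes for the retained set: **BI**
when the TSS lies within 1,000 bp (inclusive) of an annotated TSS on the
*opposite* strand — the strand requirement is this package's reading of
divergent-promoter geometry; then **AS** (class x), **OT** (class o), else
**LINC**. Coding score > 0.2 sets the TUCP flag; a pure intergenic TUCP is
named TUCP instead of LINC, while BI/AS/OT+TUCP keep the positional name with
the flag as a GTF attribute. LINC and TUCP are numbered independently,
sequentially by TSS coordinate within each chromosome (ties by transcript
id), giving stable, input-order-independent names like `HE-LINC-C7T121`;
BI/AS/OT take the associated gene's symbol (BI: nearest qualifying TSS, ties
lexicographic; AS/OT: largest exonic overlap, ties lexicographic). Naming
precedes locus collapsing, so T-numbers may show gaps in the final set.

Loci are single-linkage clusters of same-strand exonic overlap (antisense
pairs are distinct biological units and stay separate); the longest
transcript represents a locus (ties: more exons, then lexicographic id), and
transcripts of length ≤ 200 bp are removed afterwards.

Neighbourhood correlation is Pearson's r on log2(x+1) expression between each
final transcript and every annotated gene whose TSS lies within 1 Mb
(inclusive — 1,000,001 bp is out) of the transcript's TSS, on either strand.
The per-transcript summary also reports the distance to the nearest annotated
TSS on the chromosome (not window-limited), the best-|r| neighbour with its
distance, and the mean neighbour distance as the random expectation.

## Synthetic data

The default atlas mirrors a 32-sample embryonic design: 15 organ/tissue
sites with two replicates attached as sister leaves under a tissue node,
grouped into ectoderm / mesoderm / endoderm clades, plus a pluripotent
stem-cell pair — 32 leaves, hence 31 expected axes.

`simulate_lineage_counts` draws a per-gene baseline log2 mean from
Normal(5, 2) (median ~32 counts, heavy right tail — a realistic bulk
dynamic range), evolves it by independent Normal(0, 0.3²) steps per edge
(modest, clade-shared drift), adds planted module effects (default
experiment: 200 genes, +2.0 log2 in the endoderm clade), and samples
negative-binomial counts (size 10, i.e. moderate biological overdispersion)
with log-normal library factors (σ = 0.2). What it does **not** emulate:
GC/length bias, batch structure, correlated gene–gene noise beyond the tree,
isoform-level effects. Passing tests therefore demonstrate correctness of
the machinery and recoverability of clade-restricted programs under
realistic noise — not robustness to every artefact of real libraries.

`simulate_block_counts` uses Poisson noise around a background mean of 20
with +150 on block entries (background 0 gives the exact noise-free
pattern). The toy annotation is fully hand-placed and deterministic, with a
truth table derived by hand from the rules above; it covers every class
outcome, every discard class, and the three boundary cases (2 kb run-on,
1 kb bidirectional, 200 bp length). Problem sizes throughout the test suite
(e.g. 20 planted-block repeats at 50 restarts; a 20,000-gene atlas for the
recovery experiment) were chosen to keep the full suite in the tens of
seconds while leaving each conclusion statistically meaningful.

## Known limitations

* The LgPCA assumes one fixed, user-asserted lineage tree; uncertainty in
  the topology is not propagated.
* Cophenetic rank selection can be non-discriminating on very clean data
  (see above); the per-rank curve should be inspected.
* The transcript classifier is a simplified re-implementation of the
  assembler-comparison class codes: UTR-extension rescue, read-through
  detection beyond the single-span rule, and coding-potential scoring are out
  of scope (scores are consumed as input).
* Gene-associated transcript names are not de-duplicated; two retained
  transcripts associated with the same gene would share a name (the toy
  fixture avoids this; real runs should check).
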