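# lgatlas

Analysis toolkit for multi-tissue developmental transcriptome atlases:
**lineage-guided PCA** (LgPCA), NMF metagene extraction with consensus rank
selection, tissue-specificity scoring, and a systematic discovery/naming
pipeline for novel long non-coding transcripts.

## Who this is for

Groups profiling bulk RNA-seq across many organs or tissues of a developing
organism face a common problem: ordinary PCA and clustering separate the most
divergent tissues (brain, liver) but leave the relationships among the rest
unresolved. The tissues are not exchangeable samples — they are related by a
known developmental lineage, and expression programs are often shared by whole
clades (all foregut-endoderm derivatives, all ectoderm, ...). lgatlas provides
the analysis layer for such designs: it folds the lineage into the
decomposition, extracts tissue-characteristic metagenes, and handles the
companion task of cataloguing unannotated transcription.

## The core method

Let `X` be the column-centered (optionally unit-variance scaled) samples ×
genes expression matrix, and let `W` be the row-normalized **Abouheif
proximity** between samples on a user-defined developmental-lineage tree: for
tips *i*, *j*,

```
a_ij = 1 / Π dd(v)   over internal nodes v on the path i → j,
```

where `dd(v)` is the number of direct descendants of `v` (topology only — no
branch lengths), followed by row normalization. LgPCA diagonalizes the
lineage-weighted covariance

```
H = (1/n) Xᵀ W_s X ,     W_s = (W + Wᵀ)/2 .
```

Each eigenvalue factors as `λ_k = var(y_k) · I(y_k)`, with `y_k = X u_k` the
sample scores and `I` Moran's autocorrelation index under `W_s`. Axes with
`λ > 0` are **global** structures — related tissues score similarly, i.e.
clade-level expression programs; axes with `λ < 0` are **local** structures
where related samples diverge (replicate- or sample-level heterogeneity).
With genes ≫ samples the eigensystem is computed inside the row space of `X`
(SVD duality); the result is identical to the direct genes × genes
decomposition.

Around this core the package provides:

* `lgatlas.expression` — quantile normalization (rank-reference method with
  tie averaging) and the tissue-specificity index
  `τ = Σᵢ (1 − xᵢ/x_max) / (N−1)` on per-tissue mean expression;
* `lgatlas.metagenes` — NMF under the KL objective (Brunet multiplicative
  updates), consensus clustering over random restarts, cophenetic-correlation
  rank selection, and disjoint metagene gene sets by basis contribution > 0.8;
* `lgatlas.transcripts` — classification of assembled transcript models
  against a reference (class codes j/e/p discarded; o/x/i/u retained),
  positional lncRNA classes (BI/AS/OT/LINC, TUCP at coding score > 0.2),
  systematic `HE-…` naming, longest-per-locus filtering (> 200 bp), and
  expression correlation with all annotated genes within 1 Mb;
* `lgatlas.simulate` — generators for every input: tree-structured counts
  with planted clade modules, block matrices for NMF, and a toy annotation
  covering every transcript class.

## Worked example

```python
from lgatlas import expression, lgpca, lineage, simulate

tree = simulate.default_atlas_tree()          # 15 tissues ×2 reps + PSC pair
spec = simulate.SimulationSpec(tree=tree, n_genes=5000,
                               modules=(("endoderm", 200, 2.0),), seed=7)
counts, truth = simulate.simulate_lineage_counts(spec)
norm = expression.quantile_normalize(counts)
W = lineage.abouheif_proximity(tree)
res = lgpca.lgpca_fit(norm, W)

print(f"retained axes: {res.n_axes}")
print(res.summary().head(3).round(2))
high, low = lgpca.extreme_genes(res, "PC1", 1000)
hits = len(set(truth.gene) & set(high)) + len(set(truth.gene) & set(low))
print(f"planted endoderm module genes in PC1 extremes: {hits}/200")
test = lgpca.loading_gene_set_test(res, "PC1", truth.gene)
print(f"module vs background loadings: p = {test.p_value:.3g}, "
      f"direction = {test.direction}")
```

prints

```
retained axes: 31
     eigenvalue  variance  morans_i
PC1      440.82    492.97      0.89
PC2      333.57    372.36      0.90
PC3      104.12    191.66      0.54
planted endoderm module genes in PC1 extremes: 200/200
module vs background loadings: p = 2.79e-126, direction = low
```

The 32-sample atlas yields 31 axes; the leading axes have Moran's I near one
(strong lineage autocorrelation — global patterns), and the planted
endoderm-restricted module is recovered in full at one extreme of PC1, with
the rank-sum test on its loadings overwhelmingly significant. The sign of an
axis is arbitrary, so the module may surface at either pole.

The same stages are available from the shell:

```
lgatlas simulate --outdir sim --seed 7 --module endoderm:200:2.0
lgatlas run --config config.yaml
```

`run` executes normalize → lgpca → metagenes (→ classify → correlate when
GTFs are configured) and writes a manifest with parameters and input
checksums.

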