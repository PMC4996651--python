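"""Synthetic data generators for every pipeline stage.

Three generators cover the three analysis branches:

* :func:`simulate_lineage_counts` — bulk RNA-seq counts over the leaves of a
  developmental-lineage tree.  Per gene, a log2 mean evolves by independent
  Gaussian (Brownian) steps along every edge from the root; planted modules
  add a clade-restricted log2 effect; counts are negative-binomial with
  log-normal library-size factors.  This emulates tree-structured covariance
  with tissue-specific gene programs — the structure the lineage-guided PCA
  is designed to recover.
* :func:`simulate_block_counts` — block-structured matrices with known
  sample/gene memberships, the ground truth for NMF consensus clustering.
* :func:`make_toy_annotation` — a deterministic, hand-placed reference +
  novel-transcript GTF pair (with coding scores and a truth table) containing
  at least one instance of every transcript class outcome, including the
  boundary cases of the run-on (2 kb), bidirectional (1 kb) and length
  (200 bp) rules.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage import LineageTree, parse_newick
from .transcripts import (
    GenomeAnnotation,
    ReferenceGene,
    TranscriptModel,
)

__all__ = [
    "DEFAULT_ATLAS_NEWICK",
    "default_atlas_tree",
    "SimulationSpec",
    "simulate_lineage_counts",
    "simulate_block_counts",
    "ToyAnnotation",
    "make_toy_annotation",
    "make_neighborhood_fixture",
]

#: 32-leaf default atlas: 15 organs/tissues with 2 replicates each, grouped by
#: germ layer, plus a pluripotent stem-cell (psc) pair as the outgroup lineage.
DEFAULT_ATLAS_NEWICK = (
    "("
    "((brain_1,brain_2)brain,(spinal_cord_1,spinal_cord_2)spinal_cord,"
    "(rpe_1,rpe_2)rpe,(skin_1,skin_2)skin,(palate_1,palate_2)palate)ectoderm,"
    "((heart_1,heart_2)heart,(kidney_1,kidney_2)kidney,"
    "(adrenal_1,adrenal_2)adrenal,(gonad_1,gonad_2)gonad,"
    "(limb_1,limb_2)limb)mesoderm,"
    "((liver_1,liver_2)liver,(lung_1,lung_2)lung,(pancreas_1,pancreas_2)pancreas,"
    "(stomach_1,stomach_2)stomach,(thyroid_1,thyroid_2)thyroid)endoderm,"
    "(psc_1,psc_2)psc"
    ");"
)


def default_atlas_tree() -> LineageTree:
    return parse_newick(DEFAULT_ATLAS_NEWICK)


def tissue_map_from_leaves(leaves) -> pd.Series:
    """Sample -> tissue map derived from ``<tissue>_<replicate>`` leaf labels."""
    return pd.Series({lf: lf.rsplit("_", 1)[0] for lf in leaves}, name="tissue")


@dataclass
class SimulationSpec:
    """Parameters of the tree-structured count simulation.

    Attributes
    ----------
    tree
        Lineage tree whose leaves become the samples.
    n_genes
        Number of genes (default 20,000, a whole-transcriptome scale).
    baseline_mean, baseline_sd
        Per-gene baseline log2 mean ~ Normal(baseline_mean, baseline_sd).
    brownian_sd
        Standard deviation (log2 units) of the independent Gaussian step
        added on every tree edge, per gene.
    modules
        Planted clade modules as (clade node label, gene count, log2 effect);
        module genes gain the effect in every leaf under the clade.
    dispersion
        Negative-binomial size parameter (larger = closer to Poisson).
    lib_sigma
        Log-normal sigma of the per-sample library-size factors.
    seed
        Mandatory seed; the generator is a pure function of spec + seed.
    """

    tree: LineageTree
    n_genes: int = 20_000
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    brownian_sd: float = 0.3
    modules: tuple = ()
    dispersion: float = 10.0
    lib_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for clade, n, eff in self.modules:
            if not np.isfinite(eff):
                raise ValueError(f"non-finite module effect for clade {clade!r}")


def simulate_lineage_counts(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x sample count matrix over the tree's leaves.

    Returns
    -------
    (counts, truth)
        ``counts``: genes x samples integer DataFrame.  ``truth``: one row
        per planted module gene (columns gene, module, clade, log2_effect).
    """
    tree = spec.tree
    rng = np.random.default_rng(spec.seed)
    leaves = list(tree.leaves)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]

    logmean = {tree.root: rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)}
    # preorder walk: each edge adds an independent Gaussian step per gene
    stack = [tree.root]
    while stack:
        node = stack.pop()
        for child in tree.children.get(node, ()):
            logmean[child] = logmean[node] + rng.normal(
                0.0, spec.brownian_sd, spec.n_genes
            )
            stack.append(child)

    L = np.stack([logmean[lf] for lf in leaves], axis=1)  # genes x samples

    truth_rows = []
    offset = 0
    for m, (clade, n_mod, effect) in enumerate(spec.modules):
        members = tree.leaves_under(clade)  # raises KeyError for unknown clades
        cols = [leaves.index(lf) for lf in members]
        L[np.ix_(range(offset, offset + n_mod), cols)] += effect
        for g in genes[offset : offset + n_mod]:
            truth_rows.append(
                {"gene": g, "module": m, "clade": clade, "log2_effect": effect}
            )
        offset += n_mod

    lib = rng.lognormal(0.0, spec.lib_sigma, len(leaves))
    mu = np.exp2(L) * lib[None, :]
    p = spec.dispersion / (spec.dispersion + mu)
    counts = rng.negative_binomial(spec.dispersion, p)
    return (
        pd.DataFrame(counts, index=genes, columns=leaves),
        pd.DataFrame(truth_rows, columns=["gene", "module", "clade", "log2_effect"]),
    )


def simulate_block_counts(
    n_blocks: int = 3,
    samples_per_block: int = 4,
    genes_per_block: int = 30,
    background_noise: float = 20.0,
    seed: int = 0,
    signal: float = 150.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Block-structured counts: block genes elevated in block samples.

    ``background_noise`` is the Poisson mean of the background; at 0 the
    matrix is the exact (noise-free) signal pattern.

    Returns ``(counts, gene_truth, sample_truth)``.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_blocks * genes_per_block
    n_samples = n_blocks * samples_per_block
    genes = [f"bg{i + 1:04d}" for i in range(n_genes)]
    samples = [f"s{j + 1:02d}" for j in range(n_samples)]
    gene_block = np.repeat(np.arange(n_blocks), genes_per_block)
    sample_block = np.repeat(np.arange(n_blocks), samples_per_block)

    mean = np.full((n_genes, n_samples), float(background_noise))
    mean += signal * (gene_block[:, None] == sample_block[None, :])
    counts = rng.poisson(mean) if background_noise > 0 else mean.astype(int)
    return (
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.DataFrame({"gene": genes, "block": gene_block}),
        pd.DataFrame({"sample": samples, "block": sample_block}),
    )


# ---------------------------------------------------------------------------
# Toy annotation fixture
# ---------------------------------------------------------------------------

def _ref_gtf_text(genes: list[ReferenceGene]) -> str:
    buf = io.StringIO()
    for g in genes:
        attrs = (
            f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}"; '
            f'gene_name "{g.symbol}";'
        )
        buf.write(
            f"{g.chrom}\ttoy\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
        )
        for a, b in g.exons:
            buf.write(f"{g.chrom}\ttoy\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n")
    return buf.getvalue()


def _novel_gtf_text(transcripts: list[TranscriptModel]) -> str:
    buf = io.StringIO()
    for t in transcripts:
        attrs = f'gene_id "{t.id}"; transcript_id "{t.id}";'
        buf.write(
            f"{t.chrom}\ttoy\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
        )
        for a, b in t.exons:
            buf.write(f"{t.chrom}\ttoy\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n")
    return buf.getvalue()


@dataclass
class ToyAnnotation:
    """Deterministic toy fixture: GTF texts, coding scores and a truth table."""

    ref_gtf: str
    novel_gtf: str
    scores_tsv: str
    truth: pd.DataFrame
    reference: GenomeAnnotation = field(repr=False, default=None)
    novel: list = field(repr=False, default=None)

    def write(self, outdir) -> dict[str, str]:
        import os

        paths = {}
        for fname, text in [
            ("reference.gtf", self.ref_gtf),
            ("novel.gtf", self.novel_gtf),
            ("coding_scores.tsv", self.scores_tsv),
        ]:
            p = os.path.join(outdir, fname)
            with open(p, "w") as fh:
                fh.write(text)
            paths[fname] = p
        tp = os.path.join(outdir, "truth.tsv")
        self.truth.to_csv(tp, sep="\t", index=False)
        paths["truth.tsv"] = tp
        return paths


def make_toy_annotation(seed: int = 0) -> ToyAnnotation:
    """Hand-placed toy annotation exercising every transcript class outcome.

    The fixture is fully deterministic (the seed is accepted for interface
    symmetry with the other generators and does not alter coordinates); the
    truth table lists the expected class code, positional class, name and
    final-set membership of every novel transcript, derived by hand from the
    classification, naming and filtering rules.
    """
    ref = [
        ReferenceGene("G1", "G1", "chr7", "+", [(10_000, 10_500), (12_000, 13_000)]),
        ReferenceGene("G2", "G2", "chr7", "-", [(50_000, 51_000), (52_000, 53_000)]),
        ReferenceGene("G3", "G3", "chr7", "+", [(100_000, 102_000)]),
        ReferenceGene("G4", "G4", "chr7", "+", [(200_000, 200_500), (201_500, 202_000)]),
        ReferenceGene("G5", "G5", "chr9", "+", [(1_000, 1_500), (2_500, 3_000)]),
    ]

    def T(tid, chrom, strand, exons):
        return TranscriptModel(id=tid, chrom=chrom, strand=strand, exons=exons)

    novel = [
        T("N_J", "chr7", "+", [(9_500, 10_500), (12_000, 12_500)]),
        T("N_E", "chr7", "+", [(10_200, 12_200)]),
        T("N_P1", "chr7", "+", [(15_000, 16_000)]),     # 2,000 bp run-on gap: in
        T("N_P2", "chr7", "+", [(15_001, 16_001)]),     # 2,001 bp gap: out -> u
        T("N_O", "chr7", "+", [(101_000, 101_800)]),
        T("N_X", "chr7", "-", [(100_500, 101_500)]),
        T("N_I", "chr7", "-", [(10_600, 11_900)]),
        T("N_BI", "chr7", "-", [(9_100, 9_990)]),       # TSS 11 bp from G1 TSS
        T("N_BI2", "chr7", "+", [(53_999, 55_000)]),    # TSS exactly 1,000 bp: BI
        T("N_NB", "chr7", "-", [(197_800, 199_000)]),   # TSS 1,001 bp: not BI
        T("N_DUAL", "chr7", "-", [(199_300, 200_200)]),  # BI + TUCP dual label
        T("N_TUCP", "chr7", "+", [(300_000, 301_000)]),
        T("N_L1", "chr7", "+", [(400_000, 400_300)]),   # locus loser (300 bp)
        T("N_L2", "chr7", "+", [(400_100, 400_600), (401_000, 401_400)]),
        T("N_S1", "chr7", "+", [(500_000, 500_800)]),
        T("N_S2", "chr7", "-", [(500_200, 501_000)]),   # antisense to N_S1: own locus
        T("N_SHORT", "chr7", "+", [(600_000, 600_150)]),  # 150 bp: dropped
        T("N_200", "chr7", "+", [(610_000, 610_200)]),    # exactly 200 bp: dropped
        T("N_201", "chr7", "+", [(620_000, 620_201)]),    # 201 bp: kept
        T("N_C9B", "chr9", "+", [(50_000, 50_400)]),    # listed before N_C9A on
        T("N_C9A", "chr9", "+", [(20_000, 20_500)]),    # purpose: sorted numbering
    ]

    scores = {t.id: 0.05 for t in novel}
    scores["N_TUCP"] = 0.6
    scores["N_DUAL"] = 0.9

    truth = pd.DataFrame(
        [
            # id, class, retained, positional, tucp, name, in final set
            ("N_J", "j", False, None, False, None, False),
            ("N_E", "e", False, None, False, None, False),
            ("N_P1", "p", False, None, False, None, False),
            ("N_P2", "u", True, "LINC", False, "HE-LINC-C7T2", True),
            ("N_O", "o", True, "OT", False, "HE-OT-G3", True),
            ("N_X", "x", True, "AS", False, "HE-AS-G3", True),
            ("N_I", "i", True, "LINC", False, "HE-LINC-C7T1", True),
            ("N_BI", "u", True, "BI", False, "HE-BI-G1", True),
            ("N_BI2", "u", True, "BI", False, "HE-BI-G2", True),
            ("N_NB", "u", True, "LINC", False, "HE-LINC-C7T3", True),
            ("N_DUAL", "x", True, "BI", True, "HE-BI-G4", True),
            ("N_TUCP", "u", True, "TUCP", True, "HE-TUCP-C7T1", True),
            ("N_L1", "u", True, "LINC", False, "HE-LINC-C7T4", False),
            ("N_L2", "u", True, "LINC", False, "HE-LINC-C7T5", True),
            ("N_S1", "u", True, "LINC", False, "HE-LINC-C7T6", True),
            ("N_S2", "u", True, "LINC", False, "HE-LINC-C7T7", True),
            ("N_SHORT", "u", True, "LINC", False, "HE-LINC-C7T8", False),
            ("N_200", "u", True, "LINC", False, "HE-LINC-C7T9", False),
            ("N_201", "u", True, "LINC", False, "HE-LINC-C7T10", True),
            ("N_C9B", "u", True, "LINC", False, "HE-LINC-C9T2", True),
            ("N_C9A", "u", True, "LINC", False, "HE-LINC-C9T1", True),
        ],
        columns=[
            "transcript_id", "class_code", "retained",
            "positional_class", "tucp", "name", "in_final",
        ],
    )

    scores_tsv = "transcript_id\tscore\n" + "".join(
        f"{t.id}\t{scores[t.id]}\n" for t in novel
    )
    return ToyAnnotation(
        ref_gtf=_ref_gtf_text(ref),
        novel_gtf=_novel_gtf_text(novel),
        scores_tsv=scores_tsv,
        truth=truth,
        reference=GenomeAnnotation(ref),
        novel=novel,
    )


def make_neighborhood_fixture(seed: int = 0, n_samples: int = 16):
    """Planted distant-correlate scenario for neighbourhood correlation.

    One novel transcript sits on chr7 with five annotated genes around it.
    The gene 700 kb away shares the transcript's tissue profile (near-perfect
    correlation); the nearer genes are uncorrelated random profiles; one gene
    sits exactly at the 1 Mb window edge (included) and one at 1,000,001 bp
    (excluded).

    Returns ``(annotation, transcripts, expr_novel, expr_genes, truth)``.
    """
    rng = np.random.default_rng(seed)
    t_tss = 2_000_000
    nt = TranscriptModel(
        id="NT1", chrom="chr7", strand="+", exons=[(t_tss, t_tss + 1_000)]
    )
    offsets = {
        "GN_near1": 5_000,
        "GN_near2": -50_000,
        "GN_mid": 120_000,
        "GN_far": 700_000,
        "GN_edge_in": 1_000_000,
        "GN_edge_out": -1_000_001,
    }
    genes = [
        ReferenceGene(gid, gid, "chr7", "+", [(t_tss + off, t_tss + off + 1_000)])
        for gid, off in offsets.items()
    ]
    samples = [f"s{i + 1:02d}" for i in range(n_samples)]
    profile = np.zeros(n_samples)
    profile[: n_samples // 4] = 200.0   # expressed in a quarter of the samples
    profile += rng.uniform(0, 2, n_samples)

    expr_novel = pd.DataFrame([profile], index=["NT1"], columns=samples)
    rows = {}
    for gid in offsets:
        if gid == "GN_far":
            rows[gid] = 0.5 * profile + rng.uniform(0, 0.5, n_samples)
        else:
            rows[gid] = rng.uniform(0, 50, n_samples)
    expr_genes = pd.DataFrame(rows).T
    expr_genes.columns = samples

    truth = {
        "best_gene": "GN_far",
        "best_distance": 700_000,
        "excluded": ["GN_edge_out"],
        "nearest_distance": 5_000,
        "n_neighbors": 5,
    }
    return GenomeAnnotation(genes), [nt], expr_novel, expr_genes, truth
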