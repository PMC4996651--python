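"""Classification, naming and filtering of assembled transcript models.

Assembled transcript models (e.g. from a genome-guided assembler) are compared
with a reference annotation and given a single-letter class code describing
the relation, applied in a fixed priority order:

``j``  shares a splice junction (an exactly matching intron, same strand)
``e``  unspliced fragment inside a reference transcript crossing an
       exon/intron boundary on the same strand (pre-mRNA)
``p``  same-strand run-on starting within 2 kb downstream of a reference
       transcription termination site
``o``  exonic overlap on the same strand
``x``  exonic overlap on the opposite strand (antisense)
``i``  wholly contained in a reference intron
``u``  none of the above (intergenic/unknown)

Classes j/e/p are discarded; the retained transcripts are then assigned a
positional long-non-coding class — BI (bidirectional: TSS within 1 kb of an
annotated TSS on the opposite strand), AS (antisense), OT (overlapping) or
LINC (intergenic) — with transcripts of coding score > 0.2 flagged TUCP
(pure intergenic TUCPs replace the LINC label).  Systematic names follow
``HE-LINC-C<chrom>T<n>`` / ``HE-TUCP-C<chrom>T<n>`` with n sequential by TSS
coordinate per chromosome, and ``HE-<BI|AS|OT>-<geneSymbol>`` for the
gene-associated classes.  Finally, same-strand overlapping transcripts are
collapsed to one locus keeping the longest model, and everything of length
<= 200 bp is dropped.

Coordinates are 0-based half-open internally; GTF on disk is 1-based
inclusive, converted only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "ReferenceGene",
    "GenomeAnnotation",
    "read_transcripts_gtf",
    "read_annotation_gtf",
    "write_transcripts_gtf",
    "read_coding_scores",
    "classify_transcripts",
    "assign_names",
    "dedupe_and_filter",
    "neighborhood_correlation",
    "NeighborhoodReport",
    "DISCARDED_CLASSES",
    "RETAINED_CLASSES",
]

log = logging.getLogger(__name__)

DISCARDED_CLASSES = frozenset("jep")
RETAINED_CLASSES = frozenset("oxiu")


def _tss(strand: str, start: int, end: int) -> int:
    """Genomic coordinate of the 5'-most transcribed base (0-based)."""
    return start if strand == "+" else end - 1


@dataclass
class TranscriptModel:
    """An exon-resolved transcript model (0-based half-open exon intervals)."""

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    coding_score: float | None = None
    class_code: str | None = None
    positional_class: str | None = None
    tucp: bool = False
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"{self.id}: empty exon ({a}, {b})")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"{self.id}: overlapping exons")
            prev_end = b

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return _tss(self.strand, self.start, self.end)

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced(self) -> bool:
        return len(self.exons) > 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass
class ReferenceGene:
    """A reference gene/transcript with its exon structure."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return _tss(self.strand, self.start, self.end)

    @property
    def tts(self) -> int:
        """Coordinate of the 3'-most transcribed base (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


class GenomeAnnotation:
    """Reference genes with fast per-chromosome interval lookups."""

    def __init__(self, genes: list[ReferenceGene]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        self.chroms = sorted({g.chrom for g in self.genes})
        # exon interval trees keyed by (chrom, strand) and by chrom
        self._exons: dict[tuple[str, str], IntervalTree] = {}
        self._spans: dict[tuple[str, str], IntervalTree] = {}
        self._introns: dict[tuple[str, str], set[tuple[int, int]]] = {}
        self._intron_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            key = (g.chrom, g.strand)
            self._exons.setdefault(key, IntervalTree())
            for a, b in g.exons:
                self._exons[key].addi(a, b, g)
            self._spans.setdefault(key, IntervalTree()).addi(g.start, g.end, g)
            self._introns.setdefault(key, set()).update(g.introns)
            t = self._intron_trees.setdefault(g.chrom, IntervalTree())
            for a, b in g.introns:
                t.addi(a, b, g)

    def exon_overlaps(self, chrom: str, strand: str, start: int, end: int):
        tree = self._exons.get((chrom, strand))
        return list(tree.overlap(start, end)) if tree else []

    def span_overlaps(self, chrom: str, strand: str, start: int, end: int):
        tree = self._spans.get((chrom, strand))
        return list(tree.overlap(start, end)) if tree else []

    def has_intron(self, chrom: str, strand: str, intron: tuple[int, int]) -> bool:
        return intron in self._introns.get((chrom, strand), ())

    def containing_introns(self, chrom: str, start: int, end: int):
        tree = self._intron_trees.get(chrom)
        if not tree:
            return []
        return [iv for iv in tree.overlap(start, end) if iv.begin <= start and end <= iv.end]

    def tss_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "symbol": [g.symbol for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
            }
        )


# ---------------------------------------------------------------------------
# GTF I/O (gffutils parser; 1-based inclusive on disk)
# ---------------------------------------------------------------------------

def _iter_gtf_exons(path):
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype == "exon":
            yield feat


def read_annotation_gtf(path) -> GenomeAnnotation:
    """Read a reference annotation GTF; one ReferenceGene per transcript_id."""
    grouped: dict[str, dict] = {}
    for feat in _iter_gtf_exons(path):
        tid = feat.attributes["transcript_id"][0]
        rec = grouped.setdefault(
            tid,
            {
                "gene_id": feat.attributes.get("gene_id", [tid])[0],
                "symbol": feat.attributes.get("gene_name", [None])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
            },
        )
        rec["exons"].append((feat.start - 1, feat.end))
    genes = [
        ReferenceGene(
            gene_id=tid,
            symbol=rec["symbol"] or rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
        )
        for tid, rec in grouped.items()
    ]
    return GenomeAnnotation(genes)


def read_transcripts_gtf(path) -> list[TranscriptModel]:
    """Read assembled transcript models from a GTF (exon features)."""
    grouped: dict[str, dict] = {}
    order: list[str] = []
    for feat in _iter_gtf_exons(path):
        tid = feat.attributes["transcript_id"][0]
        if tid not in grouped:
            order.append(tid)
            grouped[tid] = {"chrom": feat.seqid, "strand": feat.strand, "exons": []}
        grouped[tid]["exons"].append((feat.start - 1, feat.end))
    return [
        TranscriptModel(id=tid, chrom=g["chrom"], strand=g["strand"], exons=g["exons"])
        for tid, g in ((t, grouped[t]) for t in order)
    ]


def write_transcripts_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Write transcript models to GTF with class/name attributes."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = [f'gene_id "{t.name or t.id}"', f'transcript_id "{t.name or t.id}"']
            attrs.append(f'original_id "{t.id}"')
            if t.class_code:
                attrs.append(f'class_code "{t.class_code}"')
            if t.positional_class:
                attrs.append(f'positional_class "{t.positional_class}"')
            if t.coding_score is not None:
                attrs.append(f'coding_score "{t.coding_score:g}"')
            attrs.append(f'tucp "{str(t.tucp).lower()}"')
            attr_str = "; ".join(attrs) + ";"
            fh.write(
                f"{t.chrom}\tlgatlas\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attr_str}\n"
            )
            for a, b in t.exons:
                fh.write(
                    f"{t.chrom}\tlgatlas\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t"
                    f"{attr_str}\n"
                )


def read_coding_scores(path) -> pd.Series:
    """Read a two-column TSV (transcript id, coding score in [0, 1])."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["transcript_id", "score"] + list(df.columns[2:])
    s = df.set_index("transcript_id")["score"].astype(float)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("coding scores must lie in [0, 1]")
    return s


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _classify_one(
    t: TranscriptModel, ref: GenomeAnnotation, runon_window: int
) -> str:
    if t.chrom not in ref.chroms:
        log.warning("%s: chromosome %s absent from reference; classified 'u'", t.id, t.chrom)
        return "u"
    # j: exact intron match on the same strand
    for intron in t.introns:
        if ref.has_intron(t.chrom, t.strand, intron):
            return "j"
    # e: unspliced fragment of a same-strand reference pre-mRNA (must cross an
    # exon/intron boundary of a containing transcript span)
    if not t.spliced:
        for iv in ref.span_overlaps(t.chrom, t.strand, t.start, t.end):
            g = iv.data
            if g.start <= t.start and t.end <= g.end and g.introns:
                hits_exon = any(a < t.end and t.start < b for a, b in g.exons)
                hits_intron = any(a < t.end and t.start < b for a, b in g.introns)
                if hits_exon and hits_intron:
                    return "e"
    # p: same-strand run-on within `runon_window` downstream of a reference TTS
    for g in (g for g in ref.genes if g.chrom == t.chrom and g.strand == t.strand):
        if t.strand == "+":
            gap = t.start - g.end
        else:
            gap = g.start - t.end
        if 0 <= gap <= runon_window:
            return "p"
    if ref.exon_overlaps(t.chrom, t.strand, t.start, t.end):
        return "o"
    other = "-" if t.strand == "+" else "+"
    if ref.exon_overlaps(t.chrom, other, t.start, t.end):
        return "x"
    if ref.containing_introns(t.chrom, t.start, t.end):
        return "i"
    return "u"


def classify_transcripts(
    novel: list[TranscriptModel],
    ref: GenomeAnnotation,
    runon_window: int = 2000,
) -> list[TranscriptModel]:
    """Assign a class code to every transcript (in place) and return the list.

    Rules are applied in priority order j > e > p > o > x > i > u; see the
    module docstring for the definitions.
    """
    for t in novel:
        t.class_code = _classify_one(t, ref, runon_window)
    return novel


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

def _chrom_label(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _nearest_opposite_tss(t: TranscriptModel, ref: GenomeAnnotation, window: int):
    """Closest annotated opposite-strand TSS within ``window`` bp, or None."""
    other = "-" if t.strand == "+" else "+"
    best = None
    for g in ref.genes:
        if g.chrom != t.chrom or g.strand != other:
            continue
        d = abs(g.tss - t.tss)
        if d <= window:
            key = (d, g.symbol)
            if best is None or key < best[0]:
                best = (key, g)
    return best[1] if best else None


def _best_overlap_gene(t: TranscriptModel, ref: GenomeAnnotation, strand: str):
    """Reference gene with the largest exonic overlap on ``strand``."""
    overlap_by_gene: dict[str, int] = {}
    gene_by_symbolid: dict[str, ReferenceGene] = {}
    for a, b in t.exons:
        for iv in ref.exon_overlaps(t.chrom, strand, a, b):
            g = iv.data
            ov = min(b, iv.end) - max(a, iv.begin)
            overlap_by_gene[g.gene_id] = overlap_by_gene.get(g.gene_id, 0) + ov
            gene_by_symbolid[g.gene_id] = g
    if not overlap_by_gene:
        return None
    best_id = min(
        overlap_by_gene, key=lambda gid: (-overlap_by_gene[gid], gene_by_symbolid[gid].symbol)
    )
    return gene_by_symbolid[best_id]


def assign_names(
    retained: list[TranscriptModel],
    ref: GenomeAnnotation,
    bi_window: int = 1000,
    tucp_threshold: float = 0.2,
    prefix: str = "HE",
) -> list[TranscriptModel]:
    """Assign positional classes and systematic names to retained transcripts.

    Every transcript must already carry a retained class code (o/x/i/u) and a
    coding score.  LINC and TUCP transcripts are numbered independently,
    sequentially by TSS coordinate within each chromosome.
    """
    for t in retained:
        if t.class_code not in RETAINED_CLASSES:
            raise ValueError(f"{t.id}: class {t.class_code!r} is not a retained class")
        if t.coding_score is None:
            raise ValueError(f"{t.id}: coding score required before naming")

    for t in retained:
        partner = _nearest_opposite_tss(t, ref, bi_window)
        if partner is not None:
            t.positional_class = "BI"
            t.name = f"{prefix}-BI-{partner.symbol}"
        elif t.class_code == "x":
            g = _best_overlap_gene(t, ref, "-" if t.strand == "+" else "+")
            t.positional_class = "AS"
            t.name = f"{prefix}-AS-{g.symbol}"
        elif t.class_code == "o":
            g = _best_overlap_gene(t, ref, t.strand)
            t.positional_class = "OT"
            t.name = f"{prefix}-OT-{g.symbol}"
        else:
            t.positional_class = "LINC"
        t.tucp = t.coding_score > tucp_threshold
        if t.positional_class == "LINC" and t.tucp:
            t.positional_class = "TUCP"

    # coordinate-sorted sequential numbering, per chromosome and class
    for cls in ("LINC", "TUCP"):
        pool = [t for t in retained if t.positional_class == cls]
        for chrom in sorted({t.chrom for t in pool}):
            members = sorted(
                (t for t in pool if t.chrom == chrom), key=lambda t: (t.tss, t.id)
            )
            for n, t in enumerate(members, start=1):
                t.name = f"{prefix}-{cls}-C{_chrom_label(chrom)}T{n}"
    return retained


# ---------------------------------------------------------------------------
# Locus collapsing and length filter
# ---------------------------------------------------------------------------

def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(
        ea < xb and xa < eb for ea, eb in a.exons for xa, xb in b.exons
    )


def dedupe_and_filter(
    named: list[TranscriptModel], min_len: int = 200
) -> tuple[list[TranscriptModel], pd.DataFrame, int]:
    """Collapse same-strand overlapping transcripts to loci; keep the longest.

    Loci are single-linkage clusters of same-strand exonic overlap (strand
    aware: antisense pairs stay separate).  The longest transcript wins a
    locus (ties: more exons, then lexicographically smaller id); transcripts
    of length <= ``min_len`` are then removed.

    Returns
    -------
    (final, tally, n_loci)
        The final transcript list, a per-positional-class tally, and the
        number of loci before the length filter.
    """
    parent = list(range(len(named)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[tuple[str, str], IntervalTree] = {}
    for idx, t in enumerate(named):
        key = (t.chrom, t.strand)
        tree = trees.setdefault(key, IntervalTree())
        for a, b in t.exons:
            for iv in tree.overlap(a, b):
                if _exonic_overlap(t, named[iv.data]):
                    union(idx, iv.data)
        for a, b in t.exons:
            tree.addi(a, b, idx)

    loci: dict[int, list[TranscriptModel]] = {}
    for idx, t in enumerate(named):
        loci.setdefault(find(idx), []).append(t)

    winners = []
    for members in loci.values():
        members.sort(key=lambda t: (-t.length, -t.n_exons, t.id))
        winners.append(members[0])
    final = sorted(
        (t for t in winners if t.length > min_len),
        key=lambda t: (t.chrom, t.start, t.id),
    )
    tally = (
        pd.Series([t.positional_class for t in final], dtype=object)
        .value_counts()
        .rename_axis("class")
        .rename("n")
        .reset_index()
    )
    return final, tally, len(loci)


# ---------------------------------------------------------------------------
# Neighborhood correlation
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodReport:
    """Per-transcript neighbour summary plus the full neighbour-level table."""

    summary: pd.DataFrame
    neighbors: pd.DataFrame
    no_neighbor: list[str] = field(default_factory=list)


def neighborhood_correlation(
    final: list[TranscriptModel],
    ref: GenomeAnnotation,
    expr_novel: pd.DataFrame,
    expr_genes: pd.DataFrame,
    window: int = 1_000_000,
) -> NeighborhoodReport:
    """Correlate each transcript's expression with annotated genes within 1 Mb.

    Distances are TSS-to-TSS; a gene is a neighbour iff |distance| <=
    ``window`` (a gene 1,000,001 bp away is out).  Correlation is Pearson's r
    on log2(x + 1) expression across the shared samples.  The per-transcript
    summary reports the distance to the nearest annotated TSS on the
    chromosome (window-independent), the best-|r| neighbour with its
    distance, and the mean |distance| of in-window neighbours as the
    random expectation.
    """
    shared = expr_novel.columns.intersection(expr_genes.columns)
    if len(shared) < 3:
        raise ValueError("need >=3 shared samples for correlation")
    ln = np.log2(expr_novel[shared].astype(float) + 1.0)
    lg = np.log2(expr_genes[shared].astype(float) + 1.0)

    tss_tab = ref.tss_table()
    summary_rows = []
    neighbor_rows = []
    empty = []
    for t in final:
        key = t.name or t.id
        chrom_genes = tss_tab[tss_tab.chrom == t.chrom]
        dists = chrom_genes.tss.to_numpy() - t.tss
        nearest = (
            int(np.abs(dists).min()) if len(chrom_genes) else np.nan
        )
        in_win = chrom_genes[np.abs(dists) <= window].assign(
            distance=dists[np.abs(dists) <= window]
        )
        best_r, best_gene, best_dist = np.nan, None, np.nan
        if in_win.empty:
            empty.append(key)
            log.warning("%s: no annotated gene within %d bp", key, window)
        for _, row in in_win.iterrows():
            r = np.nan
            if key in ln.index and row.gene_id in lg.index:
                x = ln.loc[key].to_numpy()
                y = lg.loc[row.gene_id].to_numpy()
                if np.std(x) > 0 and np.std(y) > 0:
                    r = float(np.corrcoef(x, y)[0, 1])
            neighbor_rows.append(
                {
                    "transcript": key,
                    "gene_id": row.gene_id,
                    "symbol": row.symbol,
                    "distance": int(row.distance),
                    "r": r,
                }
            )
            if np.isfinite(r) and (not np.isfinite(best_r) or abs(r) > abs(best_r)):
                best_r, best_gene, best_dist = r, row.symbol, int(row.distance)
        summary_rows.append(
            {
                "transcript": key,
                "nearest_tss_distance": nearest,
                "n_neighbors": len(in_win),
                "best_gene": best_gene,
                "best_r": best_r,
                "best_distance": best_dist,
                "mean_neighbor_distance": (
                    float(np.abs(in_win.distance).mean()) if len(in_win) else np.nan
                ),
            }
        )
    return NeighborhoodReport(
        summary=pd.DataFrame(summary_rows),
        neighbors=pd.DataFrame(neighbor_rows),
        no_neighbor=empty,
    )
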