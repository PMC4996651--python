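"""Count-matrix I/O, quantile normalization, tissue-specificity (tau), prefilters.

Matrices are plain :class:`pandas.DataFrame` objects with genes as rows and
samples as columns; the sample-to-tissue assignment travels separately as a
:class:`pandas.Series` indexed by sample id.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "read_counts_tsv",
    "read_sample_sheet",
    "validate_counts",
    "quantile_normalize",
    "tau",
    "prefilter_counts",
]

log = logging.getLogger(__name__)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column gene id, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(df)
    return df


def read_sample_sheet(path) -> pd.Series:
    """Read a sample sheet TSV (columns: sample, tissue[, batch]) to a tissue map."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "tissue"} <= set(sheet.columns):
        raise ValueError("sample sheet needs 'sample' and 'tissue' columns")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    return sheet.set_index("sample")["tissue"]


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")


def quantile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns so every sample shares one value distribution.

    For each rank r the reference value is the mean, across samples, of each
    sample's r-th order statistic.  Every entry is replaced by the reference
    value of its within-column rank; tied entries receive the mean of the
    reference values spanned by their tied ranks.
    """
    if counts.shape[0] < 1 or counts.shape[1] < 2:
        raise ValueError("quantile normalization needs >=1 gene and >=2 samples")
    X = counts.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    ref_cum = np.concatenate([[0.0], np.cumsum(ref)])

    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        svals = col[order]
        # run starts of tied values in the sorted column
        starts = np.flatnonzero(np.concatenate([[True], svals[1:] != svals[:-1]]))
        ends = np.concatenate([starts[1:], [len(svals)]])
        run_means = (ref_cum[ends] - ref_cum[starts]) / (ends - starts)
        expanded = np.repeat(run_means, ends - starts)
        out[order, j] = expanded
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def tissue_means(norm: pd.DataFrame, tissue_map: pd.Series) -> pd.DataFrame:
    """Average replicate columns to one column per tissue."""
    missing = norm.columns.difference(tissue_map.index)
    if len(missing):
        raise ValueError(f"samples without tissue assignment: {list(missing)}")
    return norm.T.groupby(tissue_map.reindex(norm.columns)).mean().T


def tau(norm: pd.DataFrame, tissue_map: pd.Series, log2: bool = False) -> pd.Series:
    """Tissue-specificity index tau per gene, in [0, 1].

    tau = sum_i (1 - x_i / x_max) / (N - 1) over the N per-tissue mean
    expression values x_i.  0 means uniform expression, 1 single-tissue.
    Genes whose means are all zero have no defined tau and come back NaN.

    Parameters
    ----------
    log2
        Apply log2(x + 1) to the per-tissue means before scoring.
    """
    means = tissue_means(norm, tissue_map)
    if means.shape[1] < 2:
        raise ValueError("tau needs at least 2 tissues")
    if (means.to_numpy() < 0).any():
        raise ValueError("tau is defined for non-negative expression")
    M = means.to_numpy(dtype=float)
    if log2:
        M = np.log2(M + 1.0)
    xmax = M.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - M / xmax[:, None]).sum(axis=1) / (M.shape[1] - 1)
    t[xmax == 0] = np.nan
    return pd.Series(t, index=norm.index, name="tau")


def prefilter_counts(
    counts: pd.DataFrame,
    excluded_genes=(),
    min_total: int = 100,
) -> pd.DataFrame:
    """Drop explicitly excluded genes and genes with < ``min_total`` reads overall.

    The exclusion list is caller-supplied (e.g. Y-linked genes plus *XIST*
    ahead of NMF); a gene totalling exactly ``min_total`` reads is kept.
    """
    excluded = set(excluded_genes)
    keep = ~counts.index.isin(excluded) & (counts.sum(axis=1) >= min_total)
    out = counts.loc[keep]
    if out.empty:
        log.warning("prefilter removed every gene")
    return out
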