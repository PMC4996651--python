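"""Lineage-guided PCA (LgPCA).

Standard PCA diagonalizes the sample covariance; LgPCA instead diagonalizes
the lineage-weighted covariance

    H = (1/n) X^T W_s X,        W_s = (W + W^T) / 2,

where X is the column-centered (optionally unit-variance-scaled) samples x
genes matrix and W the row-normalized Abouheif proximity between samples on a
developmental-lineage tree.  Eigenvalues factor as lambda_k = var(y_k) I(y_k)
with y_k = X u_k the sample scores and I Moran's autocorrelation index under
W_s: positive-lambda axes are "global" structures along which related samples
are similar, negative-lambda axes "local" structures along which related
samples differ.  Because genes vastly outnumber samples, the eigensystem is
computed inside the row space of X (via SVD); the result is identical to the
direct genes x genes eigendecomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LgPCAResult",
    "lgpca_fit",
    "partition_axes",
    "extreme_genes",
    "loading_gene_set_test",
    "GeneSetTestResult",
]

log = logging.getLogger(__name__)

#: an axis is retained when |lambda| exceeds this fraction of max |lambda|
RANK_RTOL = 1e-9


@dataclass
class LgPCAResult:
    """Fitted LgPCA decomposition.

    Attributes
    ----------
    eigenvalues
        Signed eigenvalues, sorted descending; length = number of retained axes.
    scores
        Samples x axes DataFrame of y_k = X u_k (columns ``PC1``..).
    loadings
        Genes x axes DataFrame of unit-norm eigenvectors u_k.
    variances, morans_i
        Per-axis var(y_k) = (1/n) sum y^2 and Moran's I(y_k); their product
        reproduces the eigenvalue.
    center, scale
        Per-gene centering and scaling vectors applied to the input.
    """

    eigenvalues: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variances: np.ndarray
    morans_i: np.ndarray
    center: pd.Series
    scale: pd.Series | None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def axis_names(self) -> list[str]:
        return list(self.scores.columns)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "variance": self.variances,
                "morans_i": self.morans_i,
            },
            index=self.axis_names,
        )


def lgpca_fit(
    norm: pd.DataFrame,
    prox: pd.DataFrame,
    scale: bool = True,
) -> LgPCAResult:
    """Fit the LgPCA of a genes x samples expression matrix.

    Parameters
    ----------
    norm
        Genes x samples (typically quantile-normalized) expression.
    prox
        Proximity matrix W whose index/columns exactly match the samples.
    scale
        Scale each gene to unit variance after centering (default).  A
        constant gene cannot be scaled; its column is set to zero with a
        warning.
    """
    samples = list(norm.columns)
    if norm.shape[1] < 3:
        raise ValueError("LgPCA needs at least 3 samples")
    if set(samples) != set(prox.index) or set(samples) != set(prox.columns):
        diff = set(samples) ^ set(prox.index)
        raise ValueError(f"sample/leaf label mismatch: {sorted(diff)}")

    X = norm.T.to_numpy(dtype=float)  # samples x genes
    n = X.shape[0]
    center = X.mean(axis=0)
    X = X - center
    scale_vec = None
    if scale:
        sd = X.std(axis=0, ddof=0)
        constant = sd == 0
        if constant.any():
            log.warning("%d constant gene(s) set to zero under scaling", constant.sum())
        sd_safe = np.where(constant, 1.0, sd)
        X = X / sd_safe
        X[:, constant] = 0.0
        scale_vec = pd.Series(sd, index=norm.index, name="scale")

    W = prox.loc[samples, samples].to_numpy(dtype=float)
    Ws = (W + W.T) / 2.0

    # eigensystem of H = (1/n) X^T Ws X restricted to the row space of X:
    # with X = U S V^T, eigenvectors of H with nonzero eigenvalue are V a
    # where a diagonalizes (1/n) S U^T Ws U S.
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    pos = s > s.max() * 1e-12 if s.size and s.max() > 0 else np.zeros_like(s, bool)
    U, s, Vt = U[:, pos], s[pos], Vt[pos]
    M = (s[:, None] * (U.T @ Ws @ U) * s[None, :]) / n
    M = (M + M.T) / 2.0
    evals, A = np.linalg.eigh(M)

    order = np.argsort(evals)[::-1]
    evals, A = evals[order], A[:, order]
    if evals.size:
        retained = np.abs(evals) > RANK_RTOL * np.abs(evals).max()
        evals, A = evals[retained], A[:, retained]

    loadings = Vt.T @ A                      # genes x axes, unit-norm columns
    scores = (U * s) @ A                     # samples x axes, = X @ loadings

    variances = (scores**2).sum(axis=0) / n
    ss = (scores**2).sum(axis=0)
    morans = np.einsum("ik,ij,jk->k", scores, Ws, scores) / ss

    names = [f"PC{i + 1}" for i in range(evals.size)]
    return LgPCAResult(
        eigenvalues=evals,
        scores=pd.DataFrame(scores, index=samples, columns=names),
        loadings=pd.DataFrame(loadings, index=norm.index, columns=names),
        variances=variances,
        morans_i=morans,
        center=pd.Series(center, index=norm.index, name="center"),
        scale=scale_vec,
    )


def partition_axes(result: LgPCAResult, n_global: int):
    """Split axes into global (first ``n_global``) and local (rest).

    Axes are in eigenvalue-descending order, so the split keeps the
    convention that global patterns (related samples similar) occupy the
    early components.  Also returns the sign-based suggestion: the axes with
    positive eigenvalue, natural candidates for the global set.

    Returns
    -------
    (global_axes, local_axes, suggested_global) : tuple of lists of axis names
    """
    if not 0 <= n_global <= result.n_axes:
        raise ValueError(f"n_global must be in [0, {result.n_axes}], got {n_global}")
    names = result.axis_names
    suggested = [nm for nm, ev in zip(names, result.eigenvalues) if ev > 0]
    return names[:n_global], names[n_global:], suggested


def extreme_genes(result: LgPCAResult, axis: str | int, k: int):
    """The k most extreme genes at either pole of one axis.

    Returns ``(high, low)``: the k genes with the largest and the k with the
    most negative loadings.  Ties break deterministically by gene id
    (lexicographically smaller id wins).
    """
    names = result.axis_names
    if isinstance(axis, int):
        if not 0 <= axis < len(names):
            raise IndexError(f"axis {axis} out of range (0..{len(names) - 1})")
        axis = names[axis]
    elif axis not in names:
        raise IndexError(f"unknown axis {axis!r}")
    v = result.loadings[axis]
    if k > len(v) // 2:
        raise ValueError(f"k={k} exceeds half the gene count ({len(v)})")
    # stable lexicographic tie-break: sort by (value, gene id)
    frame = v.rename("loading").rename_axis("gene").reset_index()
    asc = frame.sort_values(["loading", "gene"], ascending=[True, True])
    low = list(asc["gene"].iloc[:k])
    desc = frame.sort_values(["loading", "gene"], ascending=[False, True])
    high = list(desc["gene"].iloc[:k])
    return high, low


@dataclass
class GeneSetTestResult:
    """Wilcoxon rank-sum comparison of a gene set's loadings against the rest."""

    axis: str
    set_size: int
    p_value: float | None
    direction: str | None          # "high" or "low" pole
    rank_biserial: float | None
    skipped: bool = False
    reason: str | None = None


def loading_gene_set_test(
    result: LgPCAResult,
    axis: str | int,
    gene_set,
    min_size: int = 10,
) -> GeneSetTestResult:
    """Two-sided Wilcoxon rank-sum test of in-set vs out-of-set loadings.

    Sets of ``min_size`` or fewer genes are skipped (strict: a set of exactly
    ``min_size`` genes does not run).  Genes absent from the loadings matrix
    are dropped with a warning before testing.
    """
    names = result.axis_names
    if isinstance(axis, int):
        axis = names[axis]
    if axis not in names:
        raise IndexError(f"unknown axis {axis!r}")
    v = result.loadings[axis]
    in_set = v.index.intersection(pd.Index(gene_set))
    dropped = len(set(gene_set)) - len(in_set)
    if dropped:
        log.warning("%d gene(s) of the set absent from the loadings", dropped)
    if len(in_set) <= min_size:
        return GeneSetTestResult(
            axis=axis, set_size=len(in_set), p_value=None, direction=None,
            rank_biserial=None, skipped=True, reason="set_too_small",
        )
    x = v.loc[in_set].to_numpy()
    y = v.drop(in_set).to_numpy()
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    rb = 2.0 * res.statistic / (len(x) * len(y)) - 1.0
    return GeneSetTestResult(
        axis=axis,
        set_size=len(in_set),
        p_value=float(res.pvalue),
        direction="high" if rb > 0 else "low",
        rank_biserial=float(rb),
    )
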