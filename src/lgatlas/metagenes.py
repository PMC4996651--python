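"""NMF metagene extraction with consensus-based rank selection.

Non-negative matrix factorization V ~ W H (genes x r times r x samples) under
the Kullback-Leibler objective with Brunet's multiplicative updates.  The
factorization rank r is chosen by consensus clustering: over many random
restarts, samples are assigned to the metagene with the largest coefficient;
the run-averaged connectivity (consensus) matrix is scored by the cophenetic
correlation of its average-linkage dendrogram, and the rank maximizing that
coefficient wins.  Metagene-specific gene sets come from row-normalized basis
contributions above a strict threshold (> 0.5 guarantees disjoint sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NMFModel",
    "ConsensusResult",
    "nmf_brunet",
    "consensus_select_rank",
    "metagene_genes",
    "metagene_score",
]

log = logging.getLogger(__name__)

_EPS = np.finfo(float).tiny


@dataclass
class NMFModel:
    """One fitted NMF factorization V ~ basis @ coef."""

    basis: pd.DataFrame          # genes x r
    coef: pd.DataFrame           # r x samples
    rank: int
    kl_trace: np.ndarray         # KL divergence after each iteration
    seed: int
    n_iter: int
    converged: bool

    @property
    def kl(self) -> float:
        return float(self.kl_trace[-1])

    def sample_assignments(self) -> pd.Series:
        """Metagene index (0-based) with maximal coefficient, per sample."""
        return pd.Series(
            np.argmax(self.coef.to_numpy(), axis=0), index=self.coef.columns
        )


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    d = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(d)


def nmf_brunet(
    V: pd.DataFrame,
    r: int,
    max_iter: int = 2000,
    seed: int = 0,
    check_interval: int = 10,
    stall_checks: int | None = 4,
) -> NMFModel:
    """Fit NMF by Brunet's multiplicative KL updates from a seeded random start.

    Initial factors are drawn U(0, max(V)/r).  Iteration stops at
    ``max_iter`` or once the sample-connectivity matrix (from argmax
    coefficient assignments) has been unchanged for ``stall_checks``
    consecutive checks spaced ``check_interval`` iterations apart; pass
    ``stall_checks=None`` to always run the full ``max_iter`` iterations.

    Raises
    ------
    ValueError
        If ``r`` >= min(matrix dimensions), or an all-zero row/column makes
        the KL objective degenerate (the offender is named).
    """
    X = V.to_numpy(dtype=float)
    f, n = X.shape
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if r >= min(f, n):
        raise ValueError(f"rank {r} must be < min(genes, samples) = {min(f, n)}")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero gene row: {V.index[zero_rows[0]]!r}")
    zero_cols = np.flatnonzero(X.sum(axis=0) == 0)
    if zero_cols.size:
        raise ValueError(f"all-zero sample column: {V.columns[zero_cols[0]]!r}")

    rng = np.random.default_rng(seed)
    hi = X.max() / r
    W = rng.uniform(_EPS, hi, size=(f, r))
    H = rng.uniform(_EPS, hi, size=(r, n))

    trace = []
    prev_conn = None
    stall = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        H *= (W.T @ (X / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        WH = W @ H + _EPS
        W *= ((X / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        trace.append(_kl_divergence(X, W @ H + _EPS))
        if stall_checks is not None and it % check_interval == 0:
            assign = np.argmax(H, axis=0)
            conn = assign[:, None] == assign[None, :]
            if prev_conn is not None and np.array_equal(conn, prev_conn):
                stall += 1
                if stall >= stall_checks:
                    converged = True
                    break
            else:
                stall = 0
            prev_conn = conn

    return NMFModel(
        basis=pd.DataFrame(W, index=V.index, columns=range(r)),
        coef=pd.DataFrame(H, index=range(r), columns=V.columns),
        rank=r,
        kl_trace=np.asarray(trace),
        seed=seed,
        n_iter=it,
        converged=converged,
    )


@dataclass
class ConsensusResult:
    """Consensus matrices and cophenetic coefficients over a range of ranks."""

    consensus: dict[int, pd.DataFrame]
    cophenetic: dict[int, float]
    chosen_rank: int
    stable: bool = True
    models: dict[int, list[NMFModel]] = field(default_factory=dict, repr=False)


def _cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the average-linkage tree of 1 - consensus."""
    d = squareform(1.0 - consensus, checks=False)
    if d.size == 0 or np.ptp(d) == 0:
        # all pairwise distances identical: a flat (degenerate) consensus
        return 1.0 if np.allclose(d, 0) else float("nan")
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def consensus_select_rank(
    V: pd.DataFrame,
    ranks=range(11, 19),
    runs: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    keep_models: bool = False,
) -> ConsensusResult:
    """Choose the NMF rank maximizing the cophenetic coefficient.

    For every rank, ``runs`` seeded restarts are fitted; each run's samples
    are assigned to their argmax metagene and the run-averaged connectivity
    matrix forms the consensus.  Ties on the coefficient break toward the
    smaller rank.  The result is flagged unstable when the winning
    coefficient is NaN or below 0.9 (degenerate or irreproducible
    clustering).
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty rank list")
    if runs < 2:
        raise ValueError("need at least 2 runs per rank")
    ss = np.random.SeedSequence(seed)
    consensus: dict[int, pd.DataFrame] = {}
    coph: dict[int, float] = {}
    models: dict[int, list[NMFModel]] = {}
    samples = list(V.columns)
    for r in ranks:
        child_seeds = ss.spawn(runs)
        acc = np.zeros((len(samples), len(samples)))
        fitted = []
        for cs in child_seeds:
            run_seed = int(cs.generate_state(1)[0] % (2**31))
            model = nmf_brunet(V, r, max_iter=max_iter, seed=run_seed)
            assign = model.sample_assignments().to_numpy()
            acc += assign[:, None] == assign[None, :]
            if keep_models:
                fitted.append(model)
        C = acc / runs
        consensus[r] = pd.DataFrame(C, index=samples, columns=samples)
        coph[r] = _cophenetic_coefficient(C)
        if keep_models:
            models[r] = fitted

    best = max(ranks, key=lambda r: (np.nan_to_num(coph[r], nan=-np.inf), -r))
    stable = np.isfinite(coph[best]) and coph[best] >= 0.9
    if not stable:
        log.warning(
            "rank selection unstable: best cophenetic %.3f at rank %d", coph[best], best
        )
    return ConsensusResult(
        consensus=consensus, cophenetic=coph, chosen_rank=best,
        stable=stable, models=models,
    )


def metagene_genes(model: NMFModel, threshold: float = 0.8) -> dict[int, list[str]]:
    """Assign genes to metagenes by row-normalized basis contribution.

    Gene g belongs to metagene k iff basis(g, k) / sum_j basis(g, j) exceeds
    ``threshold``.  Any threshold > 0.5 makes the sets pairwise disjoint;
    genes clearing it for no metagene (or with an all-zero basis row) stay
    unassigned.
    """
    if threshold <= 0.5:
        raise ValueError("threshold must exceed 0.5 for disjoint sets")
    B = model.basis.to_numpy(dtype=float)
    rowsum = B.sum(axis=1)
    out: dict[int, list[str]] = {k: [] for k in range(model.rank)}
    ok = rowsum > 0
    contrib = np.zeros_like(B)
    contrib[ok] = B[ok] / rowsum[ok, None]
    winners = np.argmax(contrib, axis=1)
    passed = contrib[np.arange(len(B)), winners] > threshold
    for gene, k in zip(model.basis.index[passed & ok], winners[passed & ok]):
        out[int(k)].append(gene)
    return out


def metagene_score(
    gene_sets: dict[int, list[str]],
    external_expr: pd.DataFrame,
) -> pd.DataFrame:
    """Score external samples against metagene gene sets.

    score(k, s) = mean log2(x + 1) expression of set k's genes in sample s,
    z-scored across metagenes within each sample.  A set with no gene present
    in the expression matrix gets NaN scores (with a warning).
    """
    logx = np.log2(external_expr.astype(float) + 1.0)
    rows = {}
    for k, genes in gene_sets.items():
        present = logx.index.intersection(pd.Index(genes))
        if len(present) == 0:
            log.warning("metagene %s: no genes present in external data", k)
            rows[k] = pd.Series(np.nan, index=logx.columns)
        else:
            rows[k] = logx.loc[present].mean(axis=0)
    raw = pd.DataFrame(rows).T  # metagenes x samples
    mu = raw.mean(axis=0, skipna=True)
    sd = raw.std(axis=0, ddof=0, skipna=True)
    z = (raw - mu) / sd.replace(0.0, np.nan)
    return z.fillna(0.0).where(raw.notna())
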