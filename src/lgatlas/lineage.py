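"""Developmental-lineage trees and Abouheif tip proximities.

The lineage-guided PCA weights sample covariance by how close two samples sit
on a user-defined developmental-lineage tree.  Closeness is measured with the
Abouheif proximity: the reciprocal of the product, over every internal node on
the tip-to-tip path, of that node's number of direct descendants.  Only the
topology matters; branch lengths are ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = ["LineageTree", "parse_newick", "abouheif_proximity", "write_proximity_tsv"]


@dataclass
class LineageTree:
    """Rooted, topology-only tree whose leaves are RNA-seq samples.

    Parameters
    ----------
    children
        Mapping from node id to the tuple of its children ids.  Leaves do not
        appear as keys.
    root
        Id of the root node.
    leaves
        Leaf labels in the order they appeared in the source newick string.
    """

    children: dict[str, tuple[str, ...]]
    root: str
    leaves: tuple[str, ...]
    parent: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.parent = {
            child: node for node, kids in self.children.items() for child in kids
        }
        self._validate()

    def _validate(self) -> None:
        if len(self.leaves) < 3:
            raise ValueError(
                f"lineage tree needs >=3 leaves, got {len(self.leaves)}"
            )
        if len(set(self.leaves)) != len(self.leaves):
            dupes = sorted({x for x in self.leaves if list(self.leaves).count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for node, kids in self.children.items():
            if len(kids) < 2:
                raise ValueError(
                    f"internal node {node!r} has {len(kids)} child(ren); "
                    "unifurcations must be collapsed"
                )

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(self.children)

    def n_direct_descendants(self, node: str) -> int:
        return len(self.children[node])

    def ancestors(self, node: str) -> list[str]:
        """Path from ``node``'s parent up to and including the root."""
        out = []
        while node in self.parent:
            node = self.parent[node]
            out.append(node)
        return out

    def leaves_under(self, node: str) -> tuple[str, ...]:
        """All leaf labels in the clade rooted at ``node`` (a leaf is its own clade)."""
        if node not in self.children:
            if node not in self.leaves:
                raise KeyError(f"unknown node {node!r}")
            return (node,)
        stack, out = [node], []
        while stack:
            cur = stack.pop()
            kids = self.children.get(cur)
            if kids is None:
                out.append(cur)
            else:
                stack.extend(reversed(kids))
        return tuple(out)


def parse_newick(text: str) -> LineageTree:
    """Parse a newick string into a :class:`LineageTree`.

    Branch lengths are accepted and silently discarded (the proximity measure
    is topology-only).  Internal nodes with a single child are collapsed at
    parse time: they would contribute a direct-descendant count of one, a
    multiplicative no-op.

    Raises
    ------
    ValueError
        On malformed newick (message carries the parser's position report) or
        duplicate leaf labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy error messages include line/column
        raise ValueError(f"malformed newick: {exc}") from exc

    dtree.suppress_unifurcations()

    counter = 0
    ids: dict[dendropy.Node, str] = {}
    leaves: list[str] = []
    children: dict[str, tuple[str, ...]] = {}

    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise ValueError("leaf without a label")
            ids[node] = node.taxon.label
            leaves.append(node.taxon.label)
        else:
            label = node.label
            if not label or label in ids.values():
                label = f"_node{counter}"
                counter += 1
            ids[node] = label
    for node in dtree.preorder_node_iter():
        if not node.is_leaf():
            children[ids[node]] = tuple(ids[c] for c in node.child_nodes())

    return LineageTree(children=children, root=ids[dtree.seed_node], leaves=tuple(leaves))


def _raw_proximity(tree: LineageTree) -> pd.DataFrame:
    """Symmetric path-product proximities with zero diagonal (unnormalized)."""
    leaves = tree.leaves
    anc = {lf: tree.ancestors(lf) for lf in leaves}
    depth = {lf: {a: i for i, a in enumerate(path)} for lf, path in anc.items()}
    dd = {v: tree.n_direct_descendants(v) for v in tree.internal_nodes}

    n = len(leaves)
    A = np.zeros((n, n))
    for i, li in enumerate(leaves):
        for j in range(i + 1, n):
            lj = leaves[j]
            lca = next(a for a in anc[li] if a in depth[lj])
            prod = 1.0
            for a in anc[li]:
                prod *= dd[a]
                if a == lca:
                    break
            for a in anc[lj]:
                if a == lca:
                    break
                prod *= dd[a]
            A[i, j] = A[j, i] = 1.0 / prod
    return pd.DataFrame(A, index=list(leaves), columns=list(leaves))


def abouheif_proximity(tree: LineageTree, variant: str = "Abouheif") -> pd.DataFrame:
    """Abouheif tip-proximity matrix W for the lineage-guided PCA.

    Parameters
    ----------
    tree
        Lineage tree with >=2 leaves (the :class:`LineageTree` invariant of
        >=3 already guarantees this).
    variant
        ``"Abouheif"`` (default): zero diagonal, each row divided by its sum,
        so rows sum to one.  ``"oriAbouheif"``: the original variant whose
        diagonal absorbs the deficit so that rows of the *raw* proximities sum
        to one.

    Returns
    -------
    pandas.DataFrame
        Square matrix indexed by leaf labels.
    """
    if len(tree.leaves) < 2:
        raise ValueError("proximity requires at least 2 leaves")
    raw = _raw_proximity(tree)
    if variant == "Abouheif":
        W = raw.div(raw.sum(axis=1), axis=0)
    elif variant == "oriAbouheif":
        W = raw.copy()
        np.fill_diagonal(W.values, 1.0 - raw.sum(axis=1).to_numpy())
    else:
        raise ValueError(f"unknown proximity variant {variant!r}")
    if not np.isfinite(W.to_numpy()).all():
        raise ValueError("non-finite proximity entries")
    return W


def write_proximity_tsv(W: pd.DataFrame, path) -> None:
    W.to_csv(path, sep="\t", index_label="sample")
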