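"""Rooted ultrametric trees and the tree-derived matrices used downstream.

Wraps :mod:`dendropy` for Newick I/O and exposes the matrices every
phylogenetic-signal statistic needs: the Brownian-motion covariance
``C`` (``C_ij`` = root-to-MRCA shared path length), the Pagel lambda
transform of ``C``, the topological Abouheif proximity, and the GLS
phylogenetic mean.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Malformed tree input (parse failure, duplicate tips, missing lengths)."""


class PhyloTree:
    """A rooted phylogenetic tree with branch lengths and unique tip labels.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree` with branch lengths on every
        non-root edge.

    Notes
    -----
    Tip order is the left-to-right order of leaves in the underlying
    Newick string and is preserved by every matrix this class returns.
    Polytomies are allowed.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a Newick string with branch lengths."""
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        """Serialise back to Newick (round-trips topology and lengths)."""
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ----------------------------------------------------------- validation

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise TreeError("every tip must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise TreeError("tree must have at least two tips")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            if node.edge.length is None:
                raise TreeError(
                    "missing branch length on an edge (all edges need lengths)"
                )
            if node.edge.length < 0:
                raise TreeError("negative branch length")

    # ------------------------------------------------------------ accessors

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _node_depths(self) -> dict:
        depths = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in tip order."""
        depths = self._node_depths()
        return np.array(
            [depths[leaf] for leaf in self._tree.leaf_node_iter()], dtype=float
        )

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        """All root-to-tip path lengths equal within relative tolerance."""
        d = self.tip_depths()
        ref = d.max()
        if ref == 0:
            return True
        return bool(np.all(np.abs(d - ref) <= rtol * ref))

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a copy pruned to the given tip labels.

        Raises :class:`TreeError` if any requested label is absent.
        """
        want = list(dict.fromkeys(labels))
        have = set(self.tip_labels)
        missing = [l for l in want if l not in have]
        if missing:
            raise TreeError(f"labels not in tree: {missing}")
        if len(want) < 2:
            raise TreeError("cannot prune to fewer than two tips")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in set(want)]
        clone.retain_taxa(taxa)
        # retain_taxa can leave a unifurcating root edge; keep lengths as-is
        return PhyloTree(clone)

    # ------------------------------------------------------------- matrices

    def bm_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion tip covariance.

        ``C_ij`` is the depth of the most recent common ancestor of tips
        *i* and *j*; the diagonal holds root-to-tip depths. Returns the
        matrix together with the tip-label order of its rows.
        """
        leaves = list(self._tree.leaf_node_iter())
        n = len(leaves)
        depths = self._node_depths()
        anc = {leaf: self._ancestors(leaf) for leaf in leaves}
        C = np.zeros((n, n))
        for i, a in enumerate(leaves):
            C[i, i] = depths[a]
            set_a = set(id(x) for x in anc[a])
            for j in range(i + 1, n):
                b = leaves[j]
                mrca = next(x for x in anc[b] if id(x) in set_a)
                C[i, j] = C[j, i] = depths[mrca]
        return C, self.tip_labels

    @staticmethod
    def _ancestors(node) -> list:
        """Ancestors from parent up to the root (inclusive)."""
        out = []
        p = node.parent_node
        while p is not None:
            out.append(p)
            p = p.parent_node
        return out

    def abouheif_proximity(
        self, normalize: str = "row"
    ) -> tuple[np.ndarray, list[str]]:
        """Abouheif's topological proximity between tips.

        For tips i != j, ``W_ij = 1 / prod(dd_v)`` over the internal nodes
        *v* on the path from i to j, where ``dd_v`` is the number of direct
        descendants (children) of *v*. Branch lengths play no role. The
        diagonal is zero.

        Parameters
        ----------
        normalize:
            ``"raw"`` — the symmetric matrix as defined above;
            ``"row"`` — each row divided by its sum (the weighting used in
            the Moran's-I form of the Abouheif test);
            ``"ori"`` — raw off-diagonal entries with diagonal terms chosen
            so every row sums to 1 (the original Abouheif formulation).
        """
        if self.n_tips < 2:
            raise TreeError("proximity undefined for a single tip")
        leaves = list(self._tree.leaf_node_iter())
        n = len(leaves)
        nchild = {
            node: len(node.child_nodes())
            for node in self._tree.preorder_node_iter()
            if not node.is_leaf()
        }
        anc = {leaf: self._ancestors(leaf) for leaf in leaves}
        W = np.zeros((n, n))
        for i, a in enumerate(leaves):
            ids_a = [id(x) for x in anc[a]]
            for j in range(i + 1, n):
                b = leaves[j]
                ids_b = [id(x) for x in anc[b]]
                mrca_pos_b = next(
                    k for k, xid in enumerate(ids_b) if xid in set(ids_a)
                )
                mrca_pos_a = ids_a.index(ids_b[mrca_pos_b])
                # internal nodes strictly between the tips, MRCA included once
                path = anc[a][: mrca_pos_a + 1] + anc[b][:mrca_pos_b]
                prod = 1.0
                for v in path:
                    prod *= nchild[v]
                W[i, j] = W[j, i] = 1.0 / prod
        if normalize == "raw":
            pass
        elif normalize == "row":
            W = W / W.sum(axis=1, keepdims=True)
        elif normalize == "ori":
            np.fill_diagonal(W, 1.0 - W.sum(axis=1))
        else:
            raise ValueError(f"unknown normalize mode: {normalize!r}")
        return W, self.tip_labels

    def patristic_distances(self) -> tuple[np.ndarray, list[str]]:
        """Sum of branch lengths along the path between every tip pair."""
        C, labels = self.bm_covariance()
        d = np.diag(C)
        D = d[:, None] + d[None, :] - 2.0 * C
        np.fill_diagonal(D, 0.0)
        return D, labels


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform: off-diagonal entries scaled by ``lam``.

    ``lam = 1`` returns ``C`` unchanged; ``lam = 0`` the diagonal matrix.
    Raises ``ValueError`` when ``lam`` is negative or the result is not
    positive definite.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    if lam > 1.0:
        # permitted only while the transform stays a valid covariance
        try:
            np.linalg.cholesky(Cl)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"lambda={lam} leaves C(lambda) non positive definite"
            ) from exc
    return Cl


def phylo_mean(x: np.ndarray, C: np.ndarray) -> float:
    """GLS estimate of the phylogenetic (root) mean: (1'C^-1 x)/(1'C^-1 1)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if C.shape != (n, n):
        raise ValueError("trait vector and covariance dimensions differ")
    try:
        Ci_one = np.linalg.solve(C, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular BM covariance") from exc
    return float(Ci_one @ x / Ci_one.sum())


def align_to_tree(
    labels: Sequence[str], tree_labels: Sequence[str]
) -> np.ndarray:
    """Index array mapping data rows onto tree tip order.

    Label sets must match exactly; silent reordering across mismatched
    sets is forbidden.
    """
    if set(labels) != set(tree_labels):
        only_data = sorted(set(labels) - set(tree_labels))
        only_tree = sorted(set(tree_labels) - set(labels))
        raise TreeError(
            f"tip/label mismatch: data-only {only_data}, tree-only {only_tree}"
        )
    pos = {lab: i for i, lab in enumerate(labels)}
    return np.array([pos[lab] for lab in tree_labels], dtype=int)
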