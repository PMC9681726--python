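"""Time-calibrated trees and the phylogenetic covariance structures built from them.

A :class:`Phylogeny` wraps a rooted dendropy tree with mandatory branch
lengths and exposes the path-length quantities every comparative model here
consumes:

* ``mrca_depth_matrix`` — C0[i, j] = distance from the root to the most
  recent common ancestor of tips i and j.  Under Brownian motion the trait
  covariance between two species is proportional to exactly this shared
  path length, so C0 is the BM covariance structure (rate factored out).
* ``ou_cov`` — the fixed-root Ornstein-Uhlenbeck covariance
  V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij)),
  with t_ij the MRCA depth and d_ij the patristic distance: signal decays
  with divergence at rate alpha (selection strength toward the optimum).
* ``lambda_transform`` — Pagel's lambda: off-diagonal shared branch lengths
  multiplied by lambda in [0, 1]; lambda = 1 is BM, lambda = 0 a star
  phylogeny (no signal).

Branch-length units are treated as opaque "tree units" and never rescaled.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from .errors import CholeskyError, NewickParseError, TreeError

__all__ = [
    "Phylogeny",
    "read_newick",
    "ou_cov",
    "lambda_transform",
    "cholesky_or_raise",
]


def normalize_label(label: str) -> str:
    """Exact matching after underscore/space normalization."""
    return label.replace("_", " ").strip()


class Phylogeny:
    """A rooted tree with unique tip labels and nonnegative branch lengths."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self.tip_labels: list[str] = [
            normalize_label(lf.taxon.label) for lf in tree.leaf_node_iter()
        ]
        self._index = {lab: i for i, lab in enumerate(self.tip_labels)}
        if len(self._index) != len(self.tip_labels):
            raise TreeError("duplicate tip labels after normalization")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        tree.seed_node.edge.length = None  # root edge carries no information here
        return cls(tree)

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    def _validate(self):
        n = 0
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.edge.length is None:
                raise NewickParseError("tree has an edge without a branch length")
            if node.edge.length < 0:
                raise TreeError(f"negative branch length {node.edge.length}")
        for lf in self._tree.leaf_node_iter():
            if lf.taxon is None or not lf.taxon.label:
                raise NewickParseError("unlabeled tip")
            n += 1
        if n < 1:
            raise TreeError("empty tree")

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def _depths(self) -> dict:
        depth = {self._tree.seed_node: 0.0}
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth[node] = depth[node.parent_node] + node.edge.length
        return depth

    def tip_depths(self) -> np.ndarray:
        depth = self._depths()
        out = np.empty(self.n_tips)
        for i, lf in enumerate(self._tree.leaf_node_iter()):
            out[i] = depth[lf]
        return out

    def height(self) -> float:
        """Maximum root-to-tip distance."""
        return float(self.tip_depths().max())

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.tip_depths()
        h = d.max()
        return bool(h == 0 or (h - d.min()) <= rel_tol * h)

    # -- matrices ----------------------------------------------------------

    def mrca_depth_matrix(self) -> np.ndarray:
        """n x n matrix of root-to-MRCA distances (diagonal: root-to-tip depths)."""
        n = self.n_tips
        depth = self._depths()
        C = np.zeros((n, n))
        leaf_ix = {}
        for i, lf in enumerate(self._tree.leaf_node_iter()):
            leaf_ix[lf] = i
            C[i, i] = depth[lf]
        below: dict = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = [leaf_ix[node]]
                continue
            children = [below.pop(ch) for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            merged = [ix for ch in children for ix in ch]
            below[node] = merged
        return C

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise path-length (patristic) distance matrix."""
        C = self.mrca_depth_matrix()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    def correlation_matrix(self) -> np.ndarray:
        """BM structure scaled to unit diagonal (MRCA depths / tree height).

        Only meaningful for (near-)ultrametric trees, where the diagonal is
        constant; used as the correlation matrix of phylogenetic random
        effects so their variance parameter is interpretable as a variance.
        """
        C = self.mrca_depth_matrix()
        h = self.height()
        if h <= 0:
            raise TreeError("zero-height tree has no correlation structure")
        return C / h

    # -- editing -----------------------------------------------------------

    def prune(self, keep) -> "Phylogeny":
        """Induced tree on ``keep``; pairwise path lengths are preserved and
        unary nodes created by the pruning are suppressed (lengths summed)."""
        keep = {normalize_label(k) for k in keep}
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeError(f"labels not in tree: {', '.join(sorted(missing))}")
        if len(keep) < 2:
            raise TreeError("need at least 2 tips to prune to")
        sub = self._tree.clone(depth=1)
        # drop unwanted leaves (and internal nodes that become leaves)
        while True:
            doomed = [
                lf for lf in sub.leaf_node_iter()
                if lf.taxon is None or normalize_label(lf.taxon.label) not in keep
            ]
            if not doomed:
                break
            for lf in doomed:
                lf.parent_node.remove_child(lf)
        # suppress unary internal nodes, summing edge lengths; the root is
        # kept even if unary so root-to-tip depths are preserved
        for nd in list(sub.postorder_node_iter()):
            if nd is sub.seed_node or nd.is_leaf():
                continue
            kids = nd.child_nodes()
            if len(kids) == 1:
                child = kids[0]
                child.edge.length += nd.edge.length
                parent = nd.parent_node
                parent.remove_child(nd)
                parent.add_child(child)
        sub.seed_node.edge.length = None
        return Phylogeny(sub)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths mandatory) into a Phylogeny."""
    return Phylogeny.from_newick(text)


def ou_cov(tree: Phylogeny, alpha: float, sigma2: float = 1.0) -> np.ndarray:
    """Fixed-root Ornstein-Uhlenbeck covariance matrix.

    V_ij = sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))
    with t_ij the MRCA depth and d_ij the patristic distance.  As alpha -> 0
    this tends to sigma2 * mrca_depth_matrix (the BM limit), but alpha must
    be strictly positive here.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0 (BM is the alpha->0 limit, not valid OU input)")
    if not tree.is_ultrametric():
        warnings.warn("OU covariance on a non-ultrametric tree: t_ij uses MRCA depths",
                      stacklevel=2)
    t = tree.mrca_depth_matrix()
    d = tree.patristic_matrix()
    # -expm1(-2 a t) = 1 - exp(-2 a t), accurate for tiny alpha
    return sigma2 / (2.0 * alpha) * np.exp(-alpha * d) * (-np.expm1(-2.0 * alpha * t))


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply off-diagonal entries of C by lam, keep diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda {lam} outside [0, 1]")
    out = C * lam
    np.fill_diagonal(out, np.diag(C))
    return out


def cholesky_or_raise(C: np.ndarray, what: str = "covariance structure") -> np.ndarray:
    """Lower Cholesky factor, or a diagnostic error naming the structure.

    No automatic jitter is applied: a failed factorization signals a modeling
    problem the caller should see.
    """
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise CholeskyError(f"{what} is not positive definite: {exc}") from exc
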