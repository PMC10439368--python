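"""Rooted phylogenies, Brownian-motion covariance, Pagel's λ and ancestral states.

Trees are held as dendropy objects behind a thin wrapper so that every
matrix-producing operation can enforce an explicit tip order. Branch
lengths may be in any time-like unit (the motivating dataset uses
substitutions per site), so nothing here assumes ultrametricity.

Under Brownian motion the expected among-tip covariance of a trait is
C_ij = shared root-to-MRCA path length, C_ii = root-to-tip distance.
Pagel's λ scales the off-diagonal entries of C, interpolating between a
star phylogeny (λ=0) and the full tree (λ=1); for non-ultrametric trees λ
may validly exceed 1 up to the bound keeping C(λ) positive semi-definite.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "TreeError",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "substitute_tip",
    "brownian_covariance",
    "lambda_transform",
    "lambda_max",
    "ancestral_states",
]


class TreeError(ValueError):
    """Invalid tree input or operation."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths and unique tip labels."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip label(s): {dups}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise TreeError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def root_to_tip_distances(self) -> dict[str, float]:
        self.tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )
        return {
            leaf.taxon.label: float(leaf.root_distance)
            for leaf in self.tree.leaf_node_iter()
        }

    def height(self) -> float:
        return max(self.root_to_tip_distances().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.root_to_tip_distances().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1e-300))

    def newick(self) -> str:
        return write_newick(self)


@dataclass
class PhyloCovariance:
    """Brownian-motion covariance among tips, with Pagel's λ applied.

    ``matrix[i, j]`` is the λ-scaled shared path length of tips
    ``tip_order[i]`` and ``tip_order[j]``; the diagonal holds the raw
    root-to-tip distances (λ never touches it).
    """

    tip_order: tuple[str, ...]
    matrix: np.ndarray
    lam: float = 1.0
    #: jitter added to the diagonal when a solve failed on the raw matrix
    jitter: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.tip_order)
        if self.matrix.shape != (n, n):
            raise TreeError("covariance shape does not match tip order")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise TreeError("covariance not symmetric")

    @property
    def n(self) -> int:
        return len(self.tip_order)

    def reordered(self, tip_order: list[str] | tuple[str, ...]) -> "PhyloCovariance":
        idx = [self.tip_order.index(t) for t in tip_order]
        return PhyloCovariance(
            tuple(tip_order), self.matrix[np.ix_(idx, idx)], self.lam, self.jitter
        )

    def solve(self, B: np.ndarray) -> np.ndarray:
        """C⁻¹ B via Cholesky, with a logged escalating-jitter fallback."""
        L = self.cholesky_lower()
        return cho_solve((L, True), B)

    def cholesky_lower(self) -> np.ndarray:
        scale = float(np.max(np.diag(self.matrix))) or 1.0
        try:
            return np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError:
            pass
        for eps in (1e-10, 1e-8, 1e-6, 1e-4):
            try:
                L = np.linalg.cholesky(self.matrix + eps * scale * np.eye(self.n))
            except np.linalg.LinAlgError:
                continue
            self.jitter = eps * scale
            return L
        raise np.linalg.LinAlgError("covariance not positive definite even with jitter")

    def log_det(self) -> float:
        L = self.cholesky_lower()
        return 2.0 * float(np.sum(np.log(np.diag(L))))


def read_newick(text: str, missing_length: str = "error") -> Phylogeny:
    """Parse a rooted Newick tree.

    ``missing_length`` is ``"error"`` (default) or ``"zero"`` for edges
    without a length annotation (the root edge is always allowed to lack
    one).
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            if missing_length == "zero":
                edge.length = 0.0
            else:
                raise TreeError("edge without branch length")
    return Phylogeny(tree)


def write_newick(phylogeny: Phylogeny) -> str:
    """Newick string with ≥10 significant digits on branch lengths."""
    out = io.StringIO()
    phylogeny.tree.write(
        file=out, schema="newick",
        real_value_format_specifier=".12g",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.getvalue().strip() + ("" if out.getvalue().strip().endswith(";") else ";")


def prune_to_taxa(phylogeny: Phylogeny, keep: list[str]) -> Phylogeny:
    """Retain only ``keep`` tips, collapsing degree-2 nodes by summing lengths.

    Root-to-tip distances and all pairwise shared-path lengths among the
    retained tips are preserved exactly.
    """
    labels = set(phylogeny.tip_labels)
    missing = sorted(set(keep) - labels)
    if missing:
        raise TreeError(f"tips not in tree: {missing}")
    tree = phylogeny.tree.clone(depth=1)
    tree.retain_taxa_with_labels(list(keep))
    # dendropy leaves the old root when it became degree-1; collapse it so
    # root-to-tip path lengths are carried by real edges
    tree.suppress_unifurcations()
    return Phylogeny(tree)


def substitute_tip(phylogeny: Phylogeny, old: str, new: str) -> Phylogeny:
    """Relabel tip ``old`` as ``new``; topology and branch lengths untouched.

    This mirrors grafting a species onto the position of its closest
    congener so that its branch lengths are inherited.
    """
    if new in phylogeny.tip_labels:
        raise TreeError(f"label {new!r} already present")
    tree = phylogeny.tree.clone(depth=1)
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == old:
            node = leaf
            break
    if node is None:
        raise TreeError(f"tip {old!r} not found")
    # a fresh Taxon: the old one may be shared with the source tree
    taxon = dendropy.Taxon(label=new)
    tree.taxon_namespace.add_taxon(taxon)
    node.taxon = taxon
    return Phylogeny(tree)


def brownian_covariance(
    phylogeny: Phylogeny, tip_order: list[str] | None = None
) -> PhyloCovariance:
    """Expected trait covariance among tips under Brownian motion (λ=1)."""
    tree = phylogeny.tree
    labels = phylogeny.tip_labels
    if tip_order is None:
        tip_order = labels
    if sorted(tip_order) != sorted(labels):
        raise TreeError("tip_order must be a permutation of the tip labels")
    index = {lab: i for i, lab in enumerate(tip_order)}
    n = len(tip_order)
    C = np.zeros((n, n))
    # node depth = root-to-node path length; C_ij = depth of MRCA(i, j)
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        d = 0.0 if parent is None else depth[parent] + (node.edge.length or 0.0)
        depth[node] = d
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._fm_tips = [index[node.taxon.label]]
            i = node._fm_tips[0]
            C[i, i] = depth[node]
            continue
        children = node.child_nodes()
        tipsets = [c._fm_tips for c in children]
        d = depth[node]
        for a in range(len(tipsets)):
            for b in range(a + 1, len(tipsets)):
                for i in tipsets[a]:
                    C[i, tipsets[b]] = d
                    C[np.asarray(tipsets[b]), i] = d
        node._fm_tips = [i for ts in tipsets for i in ts]
    for node in tree.preorder_node_iter():
        if hasattr(node, "_fm_tips"):
            del node._fm_tips
    return PhyloCovariance(tuple(tip_order), C, lam=1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal covariance by λ, leaving the diagonal unchanged."""
    if lam < 0:
        raise TreeError("Pagel's lambda must be non-negative")
    C = cov.matrix
    M = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    return PhyloCovariance(cov.tip_order, M, lam=lam * cov.lam)


def lambda_max(cov: PhyloCovariance, cap: float = 4.0, tol: float = 1e-6) -> float:
    """Largest λ keeping C(λ) positive semi-definite (≥1 for ultrametric trees).

    Found by bisection on the smallest eigenvalue of
    (1−λ)·diag(C) + λ·C, capped at ``cap``.
    """
    C = cov.matrix
    D = np.diag(np.diag(C))

    def min_eig(lam: float) -> float:
        return float(np.linalg.eigvalsh(lam * C + (1.0 - lam) * D).min())

    if min_eig(cap) >= -tol * float(np.max(np.diag(C))):
        return cap
    lo, hi = 1.0, cap
    if min_eig(1.0) < -tol * float(np.max(np.diag(C))):
        lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_eig(mid) >= -tol * float(np.max(np.diag(C))):
            lo = mid
        else:
            hi = mid
    return lo


def ancestral_states(
    phylogeny: Phylogeny, tip_values: dict[str, float]
) -> dict[str, float]:
    """ML ancestral states of a continuous trait under Brownian motion.

    Maximizing the joint Gaussian likelihood over internal-node states is
    the weighted least-squares problem min Σ_edges (x_child − x_parent)²/b,
    a sparse linear solve on the tree's weighted Laplacian. The root
    estimate coincides with the phylogenetic GLS mean. Internal nodes are
    keyed ``node<k>`` in preorder (root = ``node0``); tips echo their input
    values under their labels.

    Zero-length edges are handled by merging: the child is constrained
    equal to its parent.
    """
    tree = phylogeny.tree
    tips = set(phylogeny.tip_labels)
    missing = sorted(tips - set(tip_values))
    if missing:
        raise TreeError(f"missing tip value(s): {missing}")

    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    if not internal:
        raise TreeError("tree has no internal nodes")
    idx = {id(n): i for i, n in enumerate(internal)}
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    eps = 1e-12 * max(phylogeny.height(), 1.0)
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        w = 1.0 / max(node.edge.length or 0.0, eps)
        j = idx[id(parent)]
        if node.is_leaf():
            A[j, j] += w
            b[j] += w * tip_values[node.taxon.label]
        else:
            i = idx[id(node)]
            A[i, i] += w
            A[j, j] += w
            A[i, j] -= w
            A[j, i] -= w
    x = np.linalg.solve(A, b)
    out = {f"node{i}": float(x[i]) for i in range(m)}
    out.update({lab: float(tip_values[lab]) for lab in tips})
    return out
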