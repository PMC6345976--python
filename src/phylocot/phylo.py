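"""Phylogenies and phylogenetic covariance matrices.

Trees are :class:`dendropy.Tree` objects throughout.  The functions here add
the covariance conventions used by the comparative analyses in this package:

* Grafen's arbitrary ultrametric branch lengths — each node is assigned a
  height proportional to (number of descendant tips − 1), raised to an
  exponent ``rho``, and normalised so the root has height 1 and every tip
  height 0.  The resulting tree is ultrametric with root-to-tip depth 1.
* The phylogenetic variance–covariance matrix ``C``: ``C[i, j]`` is the
  branch length shared by tips *i* and *j* on their paths from the root.
  After Grafen normalisation the diagonal is 1, which makes phylogenetic
  heritability from a mixed model directly comparable to Pagel's λ.
* Pagel's λ transform: off-diagonal elements multiplied by λ ∈ [0, 1],
  diagonal untouched.

A taxonomy fallback builder nests species inside shared taxonomic ranks as
polytomies, so a defensible tree can be constructed without any external
phylogeny service.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "grafen_branch_lengths",
    "vcv",
    "lambda_transform",
    "taxonomy_fallback_tree",
]


class NewickParseError(ValueError):
    """Raised when a newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates a structural requirement."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a rooted :class:`dendropy.Tree`.

    Polytomies are allowed and branch lengths are optional (Grafen
    assignment can supply them later).  Raises :class:`NewickParseError`
    with the approximate character position for malformed input, and
    :class:`TreeValidationError` for duplicate or empty tip labels or
    trees with fewer than two tips.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        if "Duplicate" in type(exc).__name__ or "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        col = getattr(exc, "col_num", None)
        where = f" near character {col}" if col is not None else ""
        raise NewickParseError(f"malformed newick{where}: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise TreeValidationError("tree must have at least 2 tips")
    if any(not lab for lab in labels):
        raise TreeValidationError("every tip must carry a non-empty label")
    seen: set[str] = set()
    dups = sorted({lab for lab in labels if lab in seen or seen.add(lab)})
    if dups:
        raise TreeValidationError(f"duplicate tip labels: {', '.join(dups)}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to a plain newick string (labels, lengths, ';')."""
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in the tree's leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def grafen_branch_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Return a copy of ``tree`` with Grafen's arbitrary branch lengths.

    Node height = ((number of descendant tips − 1) / (total tips − 1))**rho;
    tips sit at height 0 and the root at height 1.  Branch length is the
    parent height minus the child height, so the output is ultrametric with
    root-to-tip depth exactly 1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    t = tree.clone(depth=1)
    n_total = sum(1 for _ in t.leaf_node_iter())
    if n_total < 2:
        raise TreeValidationError("Grafen lengths need at least 2 tips")
    n_tips: dict[dendropy.Node, int] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            n_tips[node] = 1
        else:
            n_tips[node] = sum(n_tips[ch] for ch in node.child_nodes())
    height = {
        node: ((n_tips[node] - 1) / (n_total - 1)) ** rho for node in t.preorder_node_iter()
    }
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = height[node.parent_node] - height[node]
    return t


@dataclass
class PhyloCovariance:
    """Species × species phylogenetic covariance matrix.

    ``matrix[i, j]`` is the shared root-to-tip path length of ``taxa[i]``
    and ``taxa[j]``; ``lam`` records a Pagel's λ scaling already applied
    (``None`` means unscaled).
    """

    taxa: list[str]
    matrix: np.ndarray
    lam: float | None = None
    jitter: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match number of taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    def index(self, species: str) -> int:
        return self.taxa.index(species)

    def submatrix(self, species: list[str]) -> "PhyloCovariance":
        """Covariance restricted to ``species`` (in the given order)."""
        missing = [s for s in species if s not in self.taxa]
        if missing:
            raise KeyError(f"species not in covariance matrix: {', '.join(missing)}")
        idx = [self.taxa.index(s) for s in species]
        return PhyloCovariance(list(species), self.matrix[np.ix_(idx, idx)], lam=self.lam)

    def ensure_psd(self, jitters: tuple[float, ...] = (0.0, 1e-12, 1e-10, 1e-8)) -> np.ndarray:
        """Cholesky factor, adding the smallest diagonal jitter that works.

        The jitter actually used is recorded on ``self.jitter``.
        """
        for j in jitters:
            try:
                L = np.linalg.cholesky(self.matrix + j * np.eye(len(self.taxa)))
            except np.linalg.LinAlgError:
                continue
            self.jitter = j
            if j > 0:
                self.matrix = self.matrix + j * np.eye(len(self.taxa))
            return L
        raise np.linalg.LinAlgError(
            "covariance matrix is not positive semi-definite even with jitter"
        )


def vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Phylogenetic variance–covariance matrix of a tree with branch lengths.

    ``C[i, j]`` is the depth of the most recent common ancestor of tips *i*
    and *j* (the shared path length from the root); ``C[i, i]`` is the
    root-to-tip depth.  Raises if any non-root branch length is missing.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): k for k, leaf in enumerate(leaves)}
    n = len(leaves)
    depth: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = node.edge.length or 0.0
        else:
            if node.edge.length is None:
                raise ValueError("tree has missing branch lengths; assign them first")
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
    C = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            k = index[id(node)]
            below[id(node)] = [k]
            C[k, k] = depth[id(node)]
        else:
            groups = [below.pop(id(ch)) for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = d
            below[id(node)] = [i for g in groups for i in g]
    return PhyloCovariance(labels, C)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's λ scaling: multiply off-diagonal entries by ``lam``.

    ``lam`` must lie in [0, 1] (the bounded-optimisation contract used by
    the PGLS profile).  λ = 1 returns an identical matrix; λ = 0 a diagonal
    one.  Applying the transform twice composes multiplicatively.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix.copy()
    d = np.diag(M).copy()
    M *= lam
    np.fill_diagonal(M, d)
    prev = 1.0 if C.lam is None else C.lam
    return PhyloCovariance(list(C.taxa), M, lam=prev * lam)


def taxonomy_fallback_tree(species: list[tuple[str, tuple[str, ...]]]) -> dendropy.Tree:
    """Build a tree by nesting shared taxonomy ranks as polytomies.

    ``species`` is a list of ``(label, ranks)`` pairs with ranks ordered
    coarse → fine (e.g. class, subclass, order, family); every species needs
    at least the coarsest rank.  Internal nodes are the shared ranks;
    ranks represented by a single species collapse (no unary nodes).
    Deterministic: children are sorted lexicographically.  Branch lengths
    are not assigned — apply :func:`grafen_branch_lengths` afterwards.
    """
    if not species:
        raise ValueError("species list is empty")
    for label, ranks in species:
        if not ranks or not ranks[0]:
            raise ValueError(f"species {label!r} lacks a coarsest taxonomy rank")

    def build(items: list[tuple[str, tuple[str, ...]]], level: int) -> str:
        if len(items) == 1:
            return items[0][0]
        groups: dict[str | None, list[tuple[str, tuple[str, ...]]]] = {}
        for label, ranks in items:
            key = ranks[level] if level < len(ranks) and ranks[level] else None
            groups.setdefault(key, []).append((label, ranks))
        parts: list[str] = []
        # species with no rank at this level attach directly as children
        for label, _ in groups.pop(None, []):
            parts.append(label)
        named = {k: v for k, v in groups.items()}
        if len(named) == 1 and not parts:
            return build(next(iter(named.values())), level + 1)
        for key in sorted(named):
            sub = build(named[key], level + 1)
            parts.append(sub)
        parts.sort()
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    newick = build(list(species), 0) + ";"
    return read_newick(newick)
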