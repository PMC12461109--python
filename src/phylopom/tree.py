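"""Tree ingestion, phylogenetic correlation matrices, and the Pagel lambda transform.

Trees are rooted, have branch lengths on every non-root edge, and are
normalized to unit root-to-tip depth before a correlation matrix is built,
so that matrix entries are shared-path fractions in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "PhyloTree",
    "PhyloCorrelation",
    "parse_newick",
    "read_newick_trees",
    "write_newick_trees",
    "correlation_from_tree",
    "lambda_transform",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural requirement."""


def _scan_newick(text: str) -> None:
    """Cheap structural scan so parse errors can name a character offset."""
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {pos}"
                )
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' at end of string (character offset {len(text)})"
        )
    if ";" not in text:
        raise NewickParseError(
            f"missing ';' terminator (character offset {len(text)})"
        )


class PhyloTree:
    """A rooted phylogenetic tree with branch lengths, backed by dendropy.

    Invariants enforced at construction: unique tip labels, branch lengths
    present and non-negative on every non-root edge.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        _scan_newick(text)
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "duplicate" in str(exc).lower():
                raise TreeValidationError(
                    f"duplicate tip labels in newick string: {exc}"
                ) from exc
            raise NewickParseError(f"newick parse failed: {exc}") from exc
        return cls(dtree)

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise TreeValidationError("tree has an unlabeled tip")
            labels.append(leaf.taxon.label)
        seen, dups = set(), set()
        for lbl in labels:
            if lbl in seen:
                dups.add(lbl)
            seen.add(lbl)
        if dups:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
        if len(labels) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if nd.edge.length is None:
                raise TreeValidationError(
                    "every non-root edge must carry a branch length"
                )
            if nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {nd.edge.length}"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self._tree.leaf_node_iter()
        }

    @property
    def depth(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = np.array(list(self.tip_depths().values()))
        dmax = depths.max()
        if dmax <= 0:
            return False
        return (dmax - depths.min()) / dmax <= rtol

    def edge_set(self) -> set[tuple[frozenset, float]]:
        """Bipartition-style edge fingerprints, for topology comparison."""
        out = set()
        for nd in self._tree.postorder_node_iter():
            if nd.parent_node is None:
                continue
            tips = frozenset(
                leaf.taxon.label for leaf in nd.leaf_iter()
            )
            out.add((tips, round(nd.edge.length, 12)))
        return out

    # -- transforms --------------------------------------------------------

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())

    def normalized(self) -> "PhyloTree":
        """Return a copy rescaled to unit root-to-tip depth."""
        d = self.depth
        if d <= 0:
            raise TreeValidationError("cannot normalize a zero-depth tree")
        out = self.copy()
        for nd in out._tree.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = nd.edge.length / d
        return out

    def prune(self, labels) -> "PhyloTree":
        labels = list(labels)
        missing = sorted(set(labels) - set(self.tip_labels))
        if missing:
            raise TreeValidationError(f"species absent from tree: {missing}")
        sub = self._tree.extract_tree_with_taxa_labels(labels=labels)
        return PhyloTree(sub)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick string into a :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def read_newick_trees(path) -> list[PhyloTree]:
    """Read a tree set: one Newick string per non-empty line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


@dataclass
class PhyloCorrelation:
    """Species-by-species phylogenetic correlation matrix.

    ``matrix[j, k]`` is the shared root-to-MRCA path length of species j and
    k divided by total tree depth; the diagonal is exactly 1.
    """

    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-8) -> None:
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if not np.allclose(self.matrix, self.matrix.T, atol=atol):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=atol):
            raise ValueError("correlation matrix diagonal must be 1")
        if self.matrix.min() < -atol or self.matrix.max() > 1 + atol:
            raise ValueError("correlation entries must lie in [0, 1]")
        if np.linalg.eigvalsh(self.matrix).min() < -1e-8:
            raise ValueError("correlation matrix is not positive semi-definite")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels) -> "PhyloCorrelation":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return PhyloCorrelation(labels, self.matrix[np.ix_(idx, idx)])


def correlation_from_tree(tree: PhyloTree, species=None,
                          rtol: float = 1e-6) -> PhyloCorrelation:
    """Build the phylogenetic correlation matrix for ``species``.

    The tree is pruned to the requested species, checked for ultrametricity
    (root-to-tip depths equal within ``rtol``), and normalized to unit depth;
    entry (j, k) is then the depth of the MRCA of j and k.
    """
    tips = tree.tip_labels
    if species is None:
        species = tips
    species = list(species)
    if len(set(species)) != len(species):
        raise TreeValidationError("requested species contain duplicates")
    missing = sorted(set(species) - set(tips))
    if missing:
        raise TreeValidationError(f"species absent from tree: {missing}")
    if set(species) != set(tips):
        tree = tree.prune(species)
    dt = tree._tree
    dt.calc_node_root_distances(return_leaf_distances_only=False)
    leaf_by_label = {lf.taxon.label: lf for lf in dt.leaf_node_iter()}
    depths = np.array([leaf_by_label[s].root_distance for s in species])
    depth = depths.mean()
    if depth <= 0:
        raise TreeValidationError("tree has zero depth")
    if (depths.max() - depths.min()) / depth > rtol:
        raise TreeValidationError(
            "tree is not ultrametric within tolerance; normalize tip depths "
            "(all root-to-tip distances must be equal) before building a "
            "correlation matrix"
        )
    idx = {s: i for i, s in enumerate(species)}
    n = len(species)
    M = np.zeros((n, n))
    # postorder sweep: tips whose MRCA is this node lie in different child
    # subtrees, and the MRCA's root distance is the shared path length
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            nd._leafset = [idx[nd.taxon.label]]
        else:
            groups = [c._leafset for c in nd.child_nodes()]
            shared = nd.root_distance / depth
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for u in groups[a]:
                        for v in groups[b]:
                            M[u, v] = shared
                            M[v, u] = shared
            nd._leafset = [x for g in groups for x in g]
    np.fill_diagonal(M, 1.0)
    return PhyloCorrelation(species, M)


def lambda_transform(C: PhyloCorrelation, lam: float) -> PhyloCorrelation:
    """Scale the off-diagonal of ``C`` by Pagel's lambda.

    Implemented as the convex combination ``lam * C + (1 - lam) * I``, which
    is identical for a unit-diagonal matrix and manifestly PSD.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    R = lam * C.matrix + (1.0 - lam) * np.eye(C.n)
    return PhyloCorrelation(list(C.labels), R)
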