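"""Distance matrices, neighbor-joining trees, bootstrap supports, newick IO.

The chemotaxonomic side of the analysis turns a species x compound
profile matrix into a Euclidean distance matrix and a neighbor-joining
(NJ) dendrogram; the genetic side enters either as a ready-made newick
tree or as a distance matrix to which the same NJ step is applied.

The NJ implementation is deterministic: among tied Q-criterion minima
the join with the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest tip) is taken, so the output does not
depend on input row order. Raw NJ branch lengths, which can be negative,
are kept on the tree as produced; :func:`clamp_negative_branch_lengths`
returns a copy suitable for variance-covariance computation, with each
negative length set to zero and the deficit pushed onto the child edges
so that root-to-tip path lengths are preserved.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "profile_distance",
    "neighbor_joining",
    "bootstrap_support",
    "patristic_distances",
    "distance_to_reference",
    "prune_tips",
    "clamp_negative_branch_lengths",
    "tip_bipartitions",
    "read_newick",
    "write_newick",
    "read_distance_csv",
]

_SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels (must be square)"
            )
        if not np.isfinite(values).all():
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(values, values.T, rtol=_SYMMETRY_RTOL, atol=1e-12):
            i, j = np.unravel_index(
                np.argmax(np.abs(values - values.T)), values.shape
            )
            raise ValueError(
                f"asymmetric distance matrix: d[{self.labels[i]},{self.labels[j]}]="
                f"{values[i, j]} but d[{self.labels[j]},{self.labels[i]}]={values[j, i]}"
            )
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="")

    def row(self, label: str) -> pd.Series:
        if label not in self.labels:
            raise KeyError(
                f"label {label!r} not in distance matrix; available: {list(self.labels)}"
            )
        i = self.labels.index(label)
        return pd.Series(self.values[i], index=list(self.labels), name=label)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    """Read a square labelled CSV distance matrix (header row = header column)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValueError(
            "distance CSV is not square-labelled: row labels "
            f"{list(df.index)} differ from column labels {list(df.columns)}"
        )
    return DistanceMatrix(tuple(df.index), df.values.astype(float))


def profile_distance(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between species profile rows."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 species to compute distances")
    values = np.asarray(matrix.values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("profile matrix contains non-finite concentrations")
    d = squareform(pdist(values, metric="euclidean"))
    return DistanceMatrix(tuple(str(s) for s in matrix.index), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Agglomerative neighbor joining (Saitou & Nei / Studier & Keppler).

    Returns an unrooted tree whose seed node is the basal trifurcation.
    Branch lengths are the raw NJ estimates and may be negative. For any
    additive input matrix the tree's patristic distances reproduce the
    input exactly (up to floating error).
    """
    n = d.n
    if n < 3:
        raise ValueError(f"neighbor joining requires >= 3 labels, got {n}")

    taxa = dendropy.TaxonNamespace(list(d.labels))
    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # smallest tip label in each active cluster
    for label in d.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)
    dist = d.values.copy()

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = dist.sum(axis=1)
        # deterministic scan: pairs ordered by (key_i, key_j), strict improvement only
        order = sorted(range(r), key=lambda i: keys[i])
        best = None
        best_q = np.inf
        for a in range(r):
            i = order[a]
            for b in range(a + 1, r):
                j = order[b]
                q = (r - 2) * dist[i, j] - row_sums[i] - row_sums[j]
                if best is None or q < best_q - 1e-12 * max(1.0, abs(best_q)):
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = dist[i, j]
        li = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        child_i, child_j = nodes[i], nodes[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = float(li)
        child_j.edge.length = float(lj)

        new_row = 0.5 * (dist[i] + dist[j] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        new_dist = np.empty((r - 1, r - 1))
        new_dist[:-1, :-1] = dist[np.ix_(keep, keep)]
        new_dist[-1, :-1] = new_row[keep]
        new_dist[:-1, -1] = new_row[keep]
        new_dist[-1, -1] = 0.0
        dist = new_dist
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # basal trifurcation: three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    root = dendropy.Node()
    for node, length in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        root.add_child(node)
        node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def clamp_negative_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Copy of ``tree`` with negative branch lengths clamped to zero.

    Each negative internal edge is set to zero and its (negative) length
    is added to the edges of its child node, preserving every
    root-to-tip path length; negative pendant edges are simply clamped.
    Processing is preorder so deficits cascade toward the tips.
    """
    clamped = tree.clone(depth=1)
    for node in clamped.preorder_node_iter():
        length = node.edge.length
        if length is None or node.parent_node is None:
            continue
        if length < 0:
            if node.is_leaf():
                node.edge.length = 0.0
            else:
                for child in node.child_nodes():
                    child.edge.length = (child.edge.length or 0.0) + length
                node.edge.length = 0.0
    return clamped


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def tip_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial tip bipartitions of an (un)rooted tree.

    Each internal edge is represented by the side of the split *not*
    containing the lexicographically smallest tip label, making the
    representation rooting-invariant.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(tips)
    splits: set[frozenset] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = frozenset(tips - below) if anchor in below else below
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    matrix: pd.DataFrame,
    b: int = 100,
    seed: int | None = None,
    percent: bool = False,
) -> dendropy.Tree:
    """NJ tree from a profile matrix with compound-resampling bootstrap supports.

    Compound columns are resampled with replacement ``b`` times; each
    replicate matrix is re-run through :func:`profile_distance` and
    :func:`neighbor_joining`, and the support of each internal edge of
    the full-data tree is the number (or percent, if ``percent``) of
    replicates containing the same tip bipartition. Supports are stored
    as internal node labels.
    """
    if b < 1:
        raise ValueError(f"bootstrap iteration count must be >= 1, got {b}")
    if matrix.shape[1] < 2:
        import warnings

        warnings.warn(
            "single-compound profile matrix: bootstrap replicates are all identical",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(profile_distance(matrix))
    counts: dict[frozenset, int] = {split: 0 for split in tip_bipartitions(tree)}
    n_compounds = matrix.shape[1]
    for _ in range(b):
        cols = rng.integers(0, n_compounds, size=n_compounds)
        rep = matrix.iloc[:, cols]
        rep_splits = tip_bipartitions(neighbor_joining(profile_distance(rep)))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(tips)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = frozenset(tips - below) if anchor in below else below
        if side in counts:
            value = counts[side]
            node.label = (
                f"{100.0 * value / b:g}" if percent else str(value)
            )
    return tree


# ---------------------------------------------------------------------------
# Distances on trees
# ---------------------------------------------------------------------------


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[dendropy.Node, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0 if parent is not None else 0.0
        depths[node] = (depths[parent] if parent is not None else 0.0) + edge
        if node.is_leaf():
            out[node.taxon.label] = depths[node]
    return out


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances, labels sorted."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(tuple(labels), d)


def distance_to_reference(
    source: dendropy.Tree | DistanceMatrix, ref: str
) -> pd.Series:
    """Distances from every other label to a reference label.

    On a tree the distances are patristic (sum of branch lengths); on a
    distance matrix they are the reference row. The reference itself is
    excluded.
    """
    if isinstance(source, DistanceMatrix):
        dm = source
    else:
        dm = patristic_distances(source)
    if ref not in dm.labels:
        raise KeyError(
            f"reference {ref!r} not found; available labels: {list(dm.labels)}"
        )
    row = dm.row(ref)
    return row.drop(ref)


def prune_tips(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on ``keep``; degree-2 nodes are suppressed additively."""
    keep = list(dict.fromkeys(keep))
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = sorted(set(keep) - tips)
    if unknown:
        raise ValueError(f"labels not in tree: {unknown}")
    if len(keep) < 3:
        raise ValueError(f"need >= 3 tips after pruning, got {len(keep)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    return pruned


# ---------------------------------------------------------------------------
# Newick IO
# ---------------------------------------------------------------------------


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string into a tree, validating tip-label uniqueness."""
    if text.count("(") != text.count(")"):
        raise ValueError(
            f"unbalanced parentheses in newick: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific parse errors
        if "duplicate" in str(exc).lower():
            raise ValueError(f"duplicate tip labels in newick: {exc}") from exc
        raise ValueError(f"invalid newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels in newick: {dupes}")
    return tree


def read_newick_file(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree as newick with branch lengths and internal labels."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    return text.strip()
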