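"""Distance-based opsin phylogenies: p-distances, NJ, UPGMA, bootstrap.

The opsin-relatedness stage works from an existing protein multiple
alignment (FASTA).  Distances are gap-excluding p-distances (the fraction
of differing sites among columns where neither sequence is gapped).
Trees are built by neighbor joining (unrooted) and by UPGMA (rooted,
ultrametric); node confidence comes from column-resampling bootstrap, the
support of an internal edge being the percentage of replicate trees that
contain the same split.  Trees are dendropy ``Tree`` objects throughout,
so Newick serialization and outgroup rerooting are standard.

Determinism: when two pairs tie for the agglomeration criterion the
lexicographically smallest label pair is joined, and all bootstrap
resampling flows from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "p_distance_matrix",
    "neighbor_joining",
    "upgma",
    "bootstrap_support",
    "tree_splits",
    "write_newick",
]

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alignment:
    """A protein multiple alignment: unique names, equal-length rows."""

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "rows", tuple(self.rows))
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("taxon names must be unique")
        if not self.rows or any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("all rows must have equal length >= 1")
        if len(self.rows[0]) < 1:
            raise ValueError("alignment must have at least 1 column")

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, columns) -> "Alignment":
        """New alignment from the given column indices (bootstrap draw)."""
        cols = np.asarray(columns, dtype=int)
        arr = np.array([list(r) for r in self.rows])
        return Alignment(self.names, tuple("".join(row) for row in arr[:, cols]))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no FASTA records")
        return cls(
            tuple(r.id for r in records), tuple(str(r.seq).upper() for r in records)
        )

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.rows):
                fh.write(f">{name}\n{row}\n")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with zero diagonal."""

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")


def p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """Gap-excluding p-distances between all sequence pairs."""
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    arr = np.array([list(r) for r in alignment.rows])
    gap = arr == "-"
    n = alignment.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.names[i]!r} "
                    f"and {alignment.names[j]!r}"
                )
            d[i, j] = d[j, i] = float((arr[i, ok] != arr[j, ok]).sum()) / m
    return DistanceMatrix(alignment.names, d)


# ---------------------------------------------------------------------------
# agglomeration


def _new_tree(labels) -> tuple[dendropy.Tree, dict]:
    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    leaves = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lab)
        leaves[lab] = node
    return tree, leaves


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining (Q-criterion), returning an unrooted tree.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch of the same join, preserving the pair's path length.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree, leaf_nodes = _new_tree(d.labels)
    # active clusters: parallel lists of sort-key (smallest leaf label) and node
    keys = list(d.labels)
    nodes = [leaf_nodes[lab] for lab in d.labels]
    dist = d.matrix.copy()

    def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_d = 0.5 * (dist[i] + dist[j] - dist[i, j])
        new_d = np.maximum(new_d, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        new_key = min(keys[i], keys[j])
        dist = np.vstack([dist[keep][:, keep], new_d[keep][None, :]])
        dist = np.hstack([dist, np.append(new_d[keep], 0.0)[:, None]])
        keys = [keys[k] for k in keep] + [new_key]
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation via the three-point formulas
    (a, b, c) = range(3)
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    for node, length in zip(nodes, (la, lb, lc)):
        tree.seed_node.add_child(node)
        node.edge.length = max(float(length), 0.0)
    tree.is_rooted = False
    return tree


def upgma(d: DistanceMatrix) -> dendropy.Tree:
    """UPGMA (average linkage), returning a rooted ultrametric tree."""
    n = len(d.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    tree, leaf_nodes = _new_tree(d.labels)
    keys = list(d.labels)
    nodes = [leaf_nodes[lab] for lab in d.labels]
    sizes = [1] * n
    heights = [0.0] * n
    dist = d.matrix.copy()
    while len(nodes) > 1:
        m = len(nodes)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (dist[i, j], pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        height = 0.5 * dist[i, j]
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(height - heights[i], 0.0)
        nodes[j].edge.length = max(height - heights[j], 0.0)
        new_d = (sizes[i] * dist[i] + sizes[j] * dist[j]) / (sizes[i] + sizes[j])
        keep = [k for k in range(m) if k not in (i, j)]
        dist = np.vstack([dist[keep][:, keep], new_d[keep][None, :]])
        dist = np.hstack([dist, np.append(new_d[keep], 0.0)[:, None]])
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]
        heights = [heights[k] for k in keep] + [height]
        nodes = [nodes[k] for k in keep] + [parent]
    root = nodes[0]
    root.parent_node = None
    tree.seed_node = root
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# splits & bootstrap


def _leaf_labels(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_splits(tree: dendropy.Tree, rooted: bool) -> dict:
    """Map each internal (non-root) node to its split.

    Rooted trees use clades (the leaf set below the node); unrooted trees
    use bipartitions, represented as a frozenset of the two sides.
    Trivial splits (single leaf / whole taxon set) are excluded.
    """
    all_leaves = _leaf_labels(tree.seed_node)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = _leaf_labels(node)
        if rooted:
            if 1 < len(below) < len(all_leaves):
                out[node] = below
        else:
            other = all_leaves - below
            if len(below) >= 2 and len(other) >= 2:
                out[node] = frozenset({below, other})
    return out


def _build(method: str, d: DistanceMatrix) -> dendropy.Tree:
    if method == "nj":
        return neighbor_joining(d)
    if method == "upgma":
        return upgma(d)
    raise ValueError(f"unknown method {method!r}; expected 'nj' or 'upgma'")


def bootstrap_support(
    alignment: Alignment,
    method: str = "nj",
    replicates: int = 1000,
    seed: int = 0,
    outgroup: str | None = None,
) -> dendropy.Tree:
    """Full-data tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``replicates`` times;
    each internal split of the full-data tree is labeled with the
    percentage of replicate trees containing it.  If ``outgroup`` is
    given, the (NJ) tree is rerooted on that leaf's edge before supports
    are attached.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if outgroup is not None and outgroup not in alignment.names:
        raise ValueError(f"outgroup {outgroup!r} not among taxa")
    rooted = method == "upgma"
    tree = _build(method, p_distance_matrix(alignment))
    rng = np.random.default_rng(seed)
    # count replicate occurrences per split of the full-data tree
    counts: dict = {}
    ncols = alignment.n_columns
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        rep_tree = _build(method, p_distance_matrix(alignment.resample_columns(cols)))
        for split in set(tree_splits(rep_tree, rooted).values()):
            counts[split] = counts.get(split, 0) + 1
    if outgroup is not None and not rooted:
        og = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == outgroup
        )
        tree.to_outgroup_position(og, update_bipartitions=False)
        tree.is_rooted = True
    for node, split in tree_splits(tree, rooted).items():
        support = 100.0 * counts.get(split, 0) / replicates
        node.label = str(int(round(support)))
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Serialize with branch lengths to 6 significant digits; internal-node
    labels carry bootstrap supports."""
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".6g",
        suppress_rooting=True,
    )
    Path(path).write_text(text)
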