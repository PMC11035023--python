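"""Distance-based phylogenetics: Poisson-correction NJ with bootstrap support.

Pairwise distances between aligned proteins use the Poisson correction
``d = -ln(1 - p)`` where ``p`` is the proportion of differing sites over
pairwise-deleted (both-ungapped) columns.  Trees are built by canonical
neighbor joining; bootstrap supports are the percentage of column-resampled
replicates containing each internal bipartition of the point-estimate tree.

Trees are dendropy objects throughout; internal node labels hold bootstrap
supports (the common Newick dialect), so externally built trees with
supports can be dropped in anywhere one of these trees is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "pc_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "read_newick",
    "write_newick",
    "tree_bipartitions",
    "node_support",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.isfinite(m).all():
            raise ValueError("distance matrix entries must be finite")
        self.matrix = m


def pc_distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Poisson-correction distances with pairwise deletion of gap columns.

    For each pair, ``p`` = mismatches / columns where both sequences are
    ungapped; ``d = -ln(1 - p)``.  A saturated pair (p = 1) or a pair with
    no comparable columns is an error — silently clamping either would
    corrupt the tree.
    """
    ids = sorted(alignment)  # canonical order: results independent of input order
    seqs = [alignment[i] for i in ids]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("alignment rows must be equal length")
    arr = np.array([list(s) for s in seqs])
    gap = (arr == "-") | (arr == ".")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            ncols = int(both.sum())
            if ncols == 0:
                raise ValueError(f"no comparable columns for pair ({ids[i]}, {ids[j]})")
            p = float((arr[i][both] != arr[j][both]).sum()) / ncols
            if p >= 1.0:
                raise ValueError(
                    f"saturated pair ({ids[i]}, {ids[j]}): p = 1, PC distance undefined"
                )
            d[i, j] = d[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(ids=ids, matrix=d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Q-criterion agglomeration), unrooted.

    Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling edge.  Ties in Q are broken by the lowest
    taxon-index pair, so the result is deterministic.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.ids)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(name)) for name in dm.ids]
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i, j]
        bi = 0.5 * dij + (sums[i] - sums[j]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0:  # clamp, transferring the deficit to the sibling edge
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = bi
        nodes[j].edge.length = bj
        for k in active:  # reduce: merged node reuses i's slot
            if k not in (i, j):
                D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)

    # final trifurcation: three-point formulas
    i, j, k = active
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = dendropy.Node()
    for idx, b in ((i, bi), (j, bj), (k, bk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(b, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 500,
    seed: int = 0,
    builder: Callable[[Mapping[str, str]], dendropy.Tree] | None = None,
) -> dendropy.Tree:
    """Column-resampled bootstrap supports on the point-estimate tree.

    ``builder`` maps an alignment to a tree (default: PC-distance NJ).
    Support for each internal bipartition of the point tree is the
    percentage of replicates containing that bipartition, written to the
    internal node labels.  Deterministic under a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = list(alignment)
    ncols = len(next(iter(alignment.values())))
    if ncols < 2:
        raise ValueError("alignment must have at least 2 columns")
    if builder is None:
        builder = lambda aln: nj_tree(pc_distance_matrix(aln))
    point = builder(alignment)
    point_bips = tree_bipartitions(point)
    counts = {bip: 0 for bip in point_bips}
    rng = np.random.default_rng(seed)
    rows = {i: np.array(list(alignment[i])) for i in ids}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_aln = {i: "".join(rows[i][cols]) for i in ids}
        try:
            rep = builder(rep_aln)
        except ValueError:
            continue  # saturated/degenerate resample supports nothing
        for bip in tree_bipartitions(rep):
            if bip in counts:
                counts[bip] += 1
    for node, bip in _internal_nodes_with_bipartitions(point):
        node.label = f"{100.0 * counts[bip] / n_reps:g}"
    return point


def _leafset(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def _internal_nodes_with_bipartitions(tree):
    all_taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_taxa)
    out = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _leafset(node)
        if len(side) < 2 or len(all_taxa - side) < 2:
            continue
        if ref in side:
            side = all_taxa - side
        out.append((node, side))
    return out


def tree_bipartitions(tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf sets (unrooted sense)."""
    return {bip for _, bip in _internal_nodes_with_bipartitions(tree)}


def node_support(node) -> float | None:
    """Bootstrap support parsed from an internal node label, if any."""
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (supports as internal node labels accepted)."""
    text = None
    p = Path(str(source))
    if p.exists():
        text = p.read_text()
    else:
        text = str(source)
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    if path is not None:
        Path(path).write_text(s)
    return s
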