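"""Orthologous gene groups (OGGs) and per-branch gain/loss counting.

An OGG is the set of genes descended from a single gene in the most recent
common ancestor of the species under study.  Ingroup genes are first
attached to reference OGGs through their winning search query, then
decomposed into ingroup OGGs by iteratively extracting well-supported
clades from gene trees, and finally each OGG's gene tree is reconciled
against the species tree to count duplications (gains) and losses on every
species-tree branch.

Reconciliation is parsimony based: gene-tree edges at or below the
bootstrap threshold are collapsed to polytomies, polytomies are resolved to
minimise duplications + losses, and — because no outgroup is used per
OGG — the gene-tree rooting is chosen exhaustively over edges to minimise
the same cost.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy

from .phylo import node_support

__all__ = [
    "OGG",
    "BranchEventTable",
    "RateSummary",
    "SpeciesTreeIndex",
    "assign_to_reference_ogg",
    "decompose_into_oggs",
    "subdivide_by_basal",
    "reconcile_counts",
    "gain_loss_rates",
]


# ------------------------------ species tree -------------------------------


class SpeciesTreeIndex:
    """Rooted binary species tree with stable node ids and LCA support.

    Node ids: leaf label for leaves, else the internal node's label when
    present, else the sorted comma-joined leaf set.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.parent: dict[str, str | None] = {}
        self.children: dict[str, list[str]] = {}
        self.depth: dict[str, int] = {}
        self.id_of_node: dict[int, str] = {}
        self.leaves: set[str] = set()
        self.node_by_id: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            nid = self._node_id(node)
            self.id_of_node[id(node)] = nid
            self.node_by_id[nid] = node
            if node.parent_node is None:
                self.parent[nid] = None
                self.depth[nid] = 0
                self.root_id = nid
            else:
                pid = self.id_of_node[id(node.parent_node)]
                self.parent[nid] = pid
                self.depth[nid] = self.depth[pid] + 1
                self.children.setdefault(pid, []).append(nid)
            if node.is_leaf():
                self.leaves.add(nid)
                self.children.setdefault(nid, [])
        for nid, kids in self.children.items():
            if len(kids) not in (0, 2):
                raise ValueError(
                    f"species tree must be binary; node {nid!r} has {len(kids)} children"
                )

    @staticmethod
    def _node_id(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        if node.label:
            return node.label
        return ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))

    def lca(self, ids: Iterable[str]) -> str:
        ids = list(ids)
        cur = ids[0]
        for other in ids[1:]:
            a, b = cur, other
            while a != b:
                if self.depth[a] >= self.depth[b]:
                    a = self.parent[a]
                else:
                    b = self.parent[b]
            cur = a
        return cur

    def branch_ids(self) -> list[str]:
        """One id per branch, keyed by the child node the branch leads into."""
        return [nid for nid in self.parent if self.parent[nid] is not None]

    def sibling(self, nid: str) -> str:
        pid = self.parent[nid]
        a, b = self.children[pid]
        return b if a == nid else a


# ------------------------------- event table -------------------------------


@dataclass
class BranchEventTable:
    """Per-branch gains/losses and per-node ancestral counts for one OGG.

    Branches are keyed by the species-tree node the branch leads into; the
    stem above the species-tree root is keyed by the root id itself.
    """

    ogg_id: str
    family: str
    gains: dict[str, int]
    losses: dict[str, int]
    ancestral: dict[str, int]  # gene count at each species-tree node
    leaf_counts: dict[str, int]  # observed members per species

    def total_gains(self) -> int:
        return sum(self.gains.values())

    def total_losses(self) -> int:
        return sum(self.losses.values())


@dataclass
class RateSummary:
    family: str
    gain_rate_per_branch: dict[str, float]
    loss_rate_per_branch: dict[str, float]
    mean_gain_rate: float
    mean_loss_rate: float


@dataclass
class OGG:
    ogg_id: str
    family: str
    members: list[str]
    provenance: str = ""


# --------------------------- reference assignment --------------------------


def assign_to_reference_ogg(
    calls: Sequence,
    regions: Sequence,
    reference_ogg_of_query: Mapping[str, str],
) -> dict[str, str]:
    """Assign each intact gene to the reference OGG of its winning query.

    A call is matched to the best-hit region on the same scaffold and
    strand overlapping its interval; the region's winning query determines
    the reference OGG.  Queries absent from the map are an error; calls
    without a surviving region are simply absent from the mapping.
    """
    by_loc: dict[tuple[str, str], list] = {}
    for r in regions:
        by_loc.setdefault((r.scaffold_id, r.strand), []).append(r)
    mapping: dict[str, str] = {}
    unmapped: set[str] = set()
    for call in calls:
        if getattr(call, "status", "intact") != "intact":
            continue
        hit = None
        for r in by_loc.get((call.scaffold_id, call.strand), []):
            if r.start < call.end and call.start < r.end:
                if hit is None or r.evalue < hit.evalue:
                    hit = r
        if hit is None:
            continue
        if hit.query_id not in reference_ogg_of_query:
            unmapped.add(hit.query_id)
            continue
        mapping[call.call_id] = reference_ogg_of_query[hit.query_id]
    if unmapped:
        raise KeyError(f"queries with no reference OGG: {sorted(unmapped)}")
    return mapping


# ---------------------------- OGG decomposition ----------------------------


def _leaf_labels(node) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def decompose_into_oggs(
    tree: dendropy.Tree,
    ingroup: Iterable[str],
    support_threshold: float = 70.0,
    basal_species: str | None = None,
    species_of: Callable[[str], str] | None = None,
    ingroup_tree_of: Callable[[frozenset[str]], dendropy.Tree] | None = None,
    family: str = "",
    ogg_prefix: str = "OGG",
) -> list[OGG]:
    """Decompose a mixed ingroup/reference gene tree into ingroup OGGs.

    If the ingroup is monophyletic the whole ingroup is one OGG.  Otherwise
    clades with bootstrap support strictly above the threshold that contain
    part (not all) of the remaining ingroup and either (i) at least one
    reference gene, or (ii) only ingroup genes but separated from the rest
    of the ingroup by reference genes (divergence predating the
    ingroup/reference split), are extracted iteratively — largest ingroup
    membership first, ties by lexicographic leaf set — until none qualify;
    the leftover ingroup genes form the final OGG.

    With ``basal_species``/``species_of``/``ingroup_tree_of`` given, each
    candidate OGG is re-examined on its ingroup-only tree and subdivided in
    two when it splits into two supported clades that each contain genes of
    the basal species and of other species.
    """
    ingroup = set(ingroup)
    all_leaves = _leaf_labels(tree.seed_node)
    if not ingroup & all_leaves:
        raise ValueError("tree contains no ingroup leaves")
    if not ingroup <= all_leaves:
        missing = sorted(ingroup - all_leaves)
        raise ValueError(f"ingroup genes absent from tree: {missing}")

    work = tree.clone(depth=1)
    remaining = set(ingroup)
    groups: list[frozenset[str]] = []

    def monophyletic(t, members) -> bool:
        leaves = _leaf_labels(t.seed_node)
        if members == leaves or len(members) == 1:
            return True
        for node in t.preorder_node_iter():
            ls = _leaf_labels(node)
            if ls == members or leaves - ls == members:
                return True
        return False

    while remaining:
        if monophyletic(work, frozenset(remaining)):
            groups.append(frozenset(remaining))
            break
        # candidate clades are subtrees of the (reference-rooted) tree whose
        # bipartition is non-trivial in the unrooted sense: a "clade" whose
        # complement holds < 2 leaves carries no grouping information
        all_leaves = _leaf_labels(work.seed_node)
        candidates = []
        for node in work.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            sup = node_support(node)
            if sup is None or sup <= support_threshold:
                continue
            side = _leaf_labels(node)
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            ing = side & remaining
            refs_inside = side - ingroup
            refs_outside = (all_leaves - side) - ingroup
            if not ing or ing == remaining:
                continue
            # (i) clade holds part of the ingroup next to >=1 reference;
            # (ii) an all-ingroup clade whose divergence from the rest of
            # the ingroup predates the ingroup/reference split
            if refs_inside or (not refs_inside and refs_outside):
                candidates.append((len(ing), tuple(sorted(ing)), side, ing))
        if not candidates:
            groups.append(frozenset(remaining))
            break
        candidates.sort(key=lambda c: (-c[0], c[1]))
        _, _, clade_leaves, ing = candidates[0]
        groups.append(frozenset(ing))
        remaining -= ing
        taxa = [t for t in work.taxon_namespace if t.label in clade_leaves]
        work.prune_taxa(taxa)
        if not remaining:
            break

    # basal-species subdivision
    final: list[frozenset[str]] = []
    for g in groups:
        if basal_species and species_of and ingroup_tree_of and len(g) >= 4:
            sub = subdivide_by_basal(
                ingroup_tree_of(g), basal_species, species_of, support_threshold
            )
            final.extend(sub if sub else [g])
        else:
            final.append(g)

    final.sort(key=lambda g: sorted(g)[0])
    return [
        OGG(
            ogg_id=f"{ogg_prefix}-{i + 1}",
            family=family,
            members=sorted(g),
            provenance=f"decomposition of {len(ingroup)} ingroup genes",
        )
        for i, g in enumerate(final)
    ]


def subdivide_by_basal(
    ogg_tree: dendropy.Tree,
    basal_species: str,
    species_of: Callable[[str], str],
    support_threshold: float = 70.0,
) -> list[frozenset[str]] | None:
    """Split a candidate OGG in two at a supported basal-species-spanning split.

    When the ingroup-only tree consists of two clades, each containing both
    basal-species genes and other-species genes, and their separation is
    supported above the threshold, the candidate is subdivided.  Returns
    the two member sets, or None when no subdivision applies.
    """
    root = ogg_tree.seed_node
    kids = root.child_nodes()
    if len(kids) != 2:
        return None
    sides = [_leaf_labels(k) for k in kids]
    sup = max((node_support(k) or 0.0) for k in kids)
    if sup <= support_threshold:
        return None
    for side in sides:
        species = {species_of(g) for g in side}
        if basal_species not in species or species == {basal_species}:
            return None
    return [frozenset(sides[0]), frozenset(sides[1])]


# ----------------------------- reconciliation ------------------------------

# gene trees are handled as nested tuples:
#   ("L", gene_id, species_id)            leaf
#   ("N", (child, child, ...))            internal (possibly a polytomy)

_MAX_RESOLUTION_COMBOS = 200_000


def _gene_tree_to_graph(tree: dendropy.Tree, species_of: Callable[[str], str],
                        support_threshold: float):
    """Unrooted adjacency graph of the gene tree with low-support edges collapsed."""
    nodes: dict[int, dict] = {}
    counter = itertools.count()

    def nid():
        return next(counter)

    adj: dict[int, set[int]] = {}
    payload: dict[int, tuple[str, str]] = {}

    def add_edge(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    idmap: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            gid = node.taxon.label
            my = nid()
            payload[my] = (gid, species_of(gid))
        else:
            my = nid()
        idmap[id(node)] = my
        adj.setdefault(my, set())
        if node.parent_node is not None:
            add_edge(my, idmap[id(node.parent_node)])

    # collapse weak internal edges (support <= threshold); redirects track
    # nodes already merged away so chains of weak edges collapse fully
    redirect: dict[int, int] = {}

    def resolve(x):
        while x in redirect:
            x = redirect[x]
        return x

    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        sup = node_support(node)
        if sup is not None and sup <= support_threshold:
            a = resolve(idmap[id(node)])
            b = resolve(idmap[id(node.parent_node)])
            if a != b:
                _contract(adj, a, b)
                redirect[a] = b

    # suppress degree-2 nodes (e.g. an artificial root)
    for v in list(adj):
        if v in adj and len(adj[v]) == 2 and v not in payload:
            x, y = adj[v]
            adj[x].discard(v)
            adj[y].discard(v)
            adj[x].add(y)
            adj[y].add(x)
            del adj[v]
    return adj, payload


def _contract(adj, a, b):
    """Merge node a into b (collapse the edge a-b)."""
    if a not in adj or b not in adj.get(a, set()):
        return
    for nb in list(adj[a]):
        if nb != b:
            adj[nb].discard(a)
            adj[nb].add(b)
            adj[b].add(nb)
    adj[b].discard(a)
    del adj[a]


def _subtree(adj, payload, v, parent):
    if v in payload:
        gid, sp = payload[v]
        return ("L", gid, sp)
    kids = tuple(_subtree(adj, payload, nb, v) for nb in sorted(adj[v]) if nb != parent)
    if len(kids) == 1:
        return kids[0]
    return ("N", kids)


def _rootings(adj, payload):
    """All rooted trees obtained by rooting the unrooted graph on each edge."""
    if len(adj) == 1:
        (v,) = adj
        yield _subtree(adj, payload, v, None)
        return
    seen = set()
    for u in sorted(adj):
        for v in sorted(adj[u]):
            if (v, u) in seen:
                continue
            seen.add((u, v))
            yield ("N", (_subtree(adj, payload, u, v), _subtree(adj, payload, v, u)))


def _resolutions(node, budget):
    """All binary resolutions of the (possibly polytomous) nested tree."""
    if node[0] == "L":
        yield node
        return
    kids = node[1]
    kid_res = []
    total = 1
    for k in kids:
        r = list(_resolutions(k, budget))
        kid_res.append(r)
        total *= len(r)
    n = len(kids)
    n_topo = 1
    for i in range(3, n + 1):
        n_topo *= 2 * i - 3
    if total * n_topo > budget:
        raise ValueError(
            f"polytomy too large to resolve exhaustively ({n} children); "
            "collapse fewer edges or supply a better-supported gene tree"
        )
    for combo in itertools.product(*kid_res):
        if n == 1:
            yield combo[0]
        elif n == 2:
            yield ("N", (combo[0], combo[1]))
        else:
            yield from _join_all(list(combo))


def _join_all(items):
    if len(items) == 1:
        yield items[0]
        return
    for t in _join_all(items[:-1]):
        yield from _insert_everywhere(t, items[-1])


def _insert_everywhere(t, x):
    yield ("N", (t, x))
    if t[0] == "N":
        a, b = t[1]
        for a2 in _insert_everywhere(a, x):
            yield ("N", (a2, b))
        for b2 in _insert_everywhere(b, x):
            yield ("N", (a, b2))


def _reconcile_rooted(root, sp: SpeciesTreeIndex):
    """LCA reconciliation of a rooted binary gene tree; per-branch events.

    Returns (gains, losses, n_dup) with gains/losses as Counters keyed by
    the species node each branch leads into (root id = the root stem).
    """
    gains: Counter = Counter()
    losses: Counter = Counter()
    ndup = 0

    def charge_losses(m_parent, m_child, parent_is_dup):
        # walk up from the child's mapping; at every species node the
        # lineage passed without leaving descendants on the other side,
        # charge one loss to that sibling branch
        chain = []  # consecutive ancestors of m_child, ending at m_parent
        x = m_child
        while x != m_parent:
            x = sp.parent[x]
            if x is None:
                raise AssertionError("child mapping not below parent mapping")
            chain.append(x)
        uppers = chain if parent_is_dup else chain[:-1]
        prev = m_child
        for y in chain:
            if y in uppers:
                a, b = sp.children[y]
                losses[b if prev == a else a] += 1
            prev = y

    def walk(node):
        nonlocal ndup
        if node[0] == "L":
            return node[2]
        a, b = node[1]
        ma, mb = walk(a), walk(b)
        m = sp.lca([ma, mb])
        is_dup = m == ma or m == mb
        if is_dup:
            ndup += 1
            gains[m] += 1
        for child_m in (ma, mb):
            if child_m != m:
                charge_losses(m, child_m, is_dup)
        return m

    m_root = walk(root)
    if m_root != sp.root_id:
        # the OGG stems from a single gene in the species MRCA: the lineage
        # descended from the species root and was lost on every side branch
        charge_losses(sp.root_id, m_root, True)
    return gains, losses, ndup


def _is_descendant(sp: SpeciesTreeIndex, node_id: str, ancestor_id: str) -> bool:
    x = node_id
    while x is not None:
        if x == ancestor_id:
            return True
        x = sp.parent[x]
    return False


def reconcile_counts(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    support_threshold: float = 70.0,
    species_of: Callable[[str], str] | None = None,
    ogg_id: str = "",
    family: str = "",
) -> BranchEventTable:
    """Per-branch gene gains and losses for one OGG by parsimony reconciliation.

    Gene-tree edges with bootstrap support at or below the threshold are
    collapsed; polytomies are resolved and the tree rooted (exhaustively
    over edges, no outgroup) to minimise duplications + losses, ties broken
    toward fewer duplications.  A duplication LCA-mapped to a species node
    is a gain on the branch leading into that node; lineages passing a
    speciation with no descendants on one side are losses on that side's
    branch.  The conservation identity (root count + gains - losses along
    any root-to-leaf path equals the observed count) is asserted on every
    call.
    """
    sp = species_tree if isinstance(species_tree, SpeciesTreeIndex) else SpeciesTreeIndex(species_tree)
    if species_of is None:
        species_of = lambda gid: gid.split("|")[0]
    leaves = [lf.taxon.label for lf in gene_tree.leaf_node_iter()]
    unknown = sorted({species_of(g) for g in leaves} - sp.leaves)
    if unknown:
        raise ValueError(f"gene leaves map to unknown species: {unknown}")

    leaf_counts = Counter(species_of(g) for g in leaves)
    branch_ids = sp.branch_ids()

    if len(leaves) == 1:
        # single gene: present along the path root -> its species, lost nowhere
        gains: Counter = Counter()
        losses: Counter = Counter()
        only = species_of(leaves[0])
        # lineages absent from all other species: losses on every branch
        # hanging off the root-to-leaf path
        x = only
        while x != sp.root_id:
            losses[sp.sibling(x)] += 1
            x = sp.parent[x]
        best = (gains, losses, 0)
    else:
        adj, payload = _gene_tree_to_graph(gene_tree, species_of, support_threshold)
        best = None
        best_key = None
        for rooted in _rootings(adj, payload):
            for resolved in _resolutions(rooted, _MAX_RESOLUTION_COMBOS):
                gains, losses, ndup = _reconcile_rooted(resolved, sp)
                # genes missing from entire species subtrees are losses too:
                # a lineage at the gene-tree root exists at its mapped node;
                # species above the root mapping never had it — no charge.
                total = sum(gains.values()) + sum(losses.values())
                key = (total, ndup, tuple(sorted(gains.items())), tuple(sorted(losses.items())))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (gains, losses, ndup)
        assert best is not None
    gains, losses, _ = best

    # ancestral counts from the conservation recurrence; the root-mapped
    # lineage chain contributes gains on the root stem
    ancestral: dict[str, int] = {}
    root_map_gains = gains.get(sp.root_id, 0)
    ancestral[sp.root_id] = 1 + root_map_gains

    def down(nid):
        for c in sp.children.get(nid, []):
            ancestral[c] = ancestral[nid] + gains.get(c, 0) - losses.get(c, 0)
            down(c)

    down(sp.root_id)
    for leaf in sp.leaves:
        if ancestral[leaf] != leaf_counts.get(leaf, 0):
            raise AssertionError(
                f"conservation violated at {leaf}: reconstructed {ancestral[leaf]}, "
                f"observed {leaf_counts.get(leaf, 0)}"
            )
    if any(v < 0 for v in ancestral.values()):
        raise AssertionError("negative ancestral gene count")

    return BranchEventTable(
        ogg_id=ogg_id,
        family=family,
        gains={b: gains.get(b, 0) for b in branch_ids + [sp.root_id]},
        losses={b: losses.get(b, 0) for b in branch_ids},
        ancestral=ancestral,
        leaf_counts=dict(leaf_counts),
    )


def gain_loss_rates(
    tables: Sequence[BranchEventTable],
    species_tree: dendropy.Tree | SpeciesTreeIndex,
    family: str = "",
) -> RateSummary:
    """Mean per-gene gain and loss rates across species-tree branches.

    Events are pooled over OGGs; each branch's rate is events divided by
    the pooled gene count at the ancestral node the branch connects to, and
    the family rate is the arithmetic mean over branches with a nonzero
    ancestral count.
    """
    sp = species_tree if isinstance(species_tree, SpeciesTreeIndex) else SpeciesTreeIndex(species_tree)
    branch_ids = sp.branch_ids()
    gain_rates: dict[str, float] = {}
    loss_rates: dict[str, float] = {}
    for b in branch_ids:
        anc = sum(t.ancestral.get(sp.parent[b], 0) for t in tables)
        g = sum(t.gains.get(b, 0) for t in tables)
        l = sum(t.losses.get(b, 0) for t in tables)
        if anc == 0:
            if g or l:
                raise ValueError(
                    f"branch into {b!r}: events with zero ancestral gene count"
                )
            continue
        gain_rates[b] = g / anc
        loss_rates[b] = l / anc
    if not gain_rates:
        return RateSummary(family, {}, {}, 0.0, 0.0)
    return RateSummary(
        family=family,
        gain_rate_per_branch=gain_rates,
        loss_rate_per_branch=loss_rates,
        mean_gain_rate=sum(gain_rates.values()) / len(gain_rates),
        mean_loss_rate=sum(loss_rates.values()) / len(loss_rates),
    )
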