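"""Independent brute-force oracles used only by the tests.

The duplication-loss oracle reconstructs an explicit embedding of a rooted
gene tree into the species tree (top-down, inserting loss events while
walking lineages to their mapped nodes) and minimises over all rootings by
rerooting with dendropy.  It shares no counting code with the package.
"""

from collections import Counter

import dendropy


def _species_index(tree):
    parent, children, ids = {}, {}, {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            nid = node.taxon.label
        else:
            nid = node.label or ",".join(
                sorted(lf.taxon.label for lf in node.leaf_iter())
            )
        ids[id(node)] = nid
        children.setdefault(nid, [])
        if node.parent_node is None:
            parent[nid] = None
            root = nid
        else:
            pid = ids[id(node.parent_node)]
            parent[nid] = pid
            children[pid].append(nid)
    return parent, children, root


def _ancestors(parent, nid):
    out = []
    while nid is not None:
        out.append(nid)
        nid = parent[nid]
    return out


def oracle_reconcile_rooted(gene_root, parent, children, sp_root, species_of):
    """Explicit embedding of a rooted binary gene tree; returns event counters.

    ``gene_root`` is a dendropy node.  Losses are inserted while walking
    each lineage from the species node it enters down to its mapping;
    a duplication is a gene node mapped to the same species node as one of
    its children, charged as a gain on the branch into that node.
    """
    gains, losses = Counter(), Counter()

    def mapping(g):
        leaves = [lf.taxon.label for lf in g.leaf_iter()]
        anc_sets = [ _ancestors(parent, species_of(l)) for l in leaves ]
        common = set(anc_sets[0])
        for s in anc_sets[1:]:
            common &= set(s)
        # deepest common ancestor = first element of any ancestor list in common
        for nid in anc_sets[0]:
            if nid in common:
                return nid
        raise AssertionError("no common ancestor")

    def _is_anc(parent_map, anc, node):
        return anc in _ancestors(parent_map, node)

    def walk_down(entry, target):
        """Insert losses from species node `entry` down to `target`."""
        s = entry
        while s != target:
            on = next(c for c in children[s] if _is_anc(parent, c, target))
            for c in children[s]:
                if c != on:
                    losses[c] += 1
            s = on
        return s

    def embed(g, entry):
        m = mapping(g)
        s = walk_down(entry, m)
        if g.is_leaf():
            return
        kids = g.child_nodes()
        assert len(kids) == 2
        maps = [mapping(k) for k in kids]
        if m in maps:  # duplication at s
            gains[s] += 1
            for k in kids:
                embed(k, s)
        else:  # speciation: each child continues into the subtree holding it
            for k, mk in zip(kids, maps):
                on = next(c for c in children[s] if _is_anc(parent, c, mk))
                embed(k, on)

    embed(gene_root, sp_root)
    return gains, losses


def oracle_min_reconcile(gene_tree, species_tree, species_of=None):
    """Min-cost per-branch (gains, losses) over all rootings of the gene tree."""
    if species_of is None:
        species_of = lambda g: g.split("|")[0]
    parent, children, sp_root = _species_index(species_tree)
    best = None
    n_leaves = len(gene_tree.leaf_nodes())
    for eidx, edge in enumerate(list(gene_tree.preorder_edge_iter())):
        if edge.head_node is gene_tree.seed_node:
            continue
        work = gene_tree.clone(depth=1)
        w_edges = [e for e in work.preorder_edge_iter() if e.head_node is not work.seed_node]
        g_edges = [e for e in gene_tree.preorder_edge_iter() if e.head_node is not gene_tree.seed_node]
        target = w_edges[g_edges.index(edge)]
        if target.length is None:
            target.length = 1.0
        work.reroot_at_edge(target, update_bipartitions=False)
        work.suppress_unifurcations()
        if len(work.seed_node.child_nodes()) != 2:
            continue
        gains, losses = oracle_reconcile_rooted(
            work.seed_node, parent, children, sp_root, species_of
        )
        total = sum(gains.values()) + sum(losses.values())
        key = (total, sum(gains.values()))
        if best is None or key < best[0]:
            best = (key, gains, losses)
    assert best is not None
    return best[1], best[2]
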