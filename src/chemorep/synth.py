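"""Synthetic inputs with known truth for every pipeline stage.

Two generators:

* :func:`plant_genome` builds multi-scaffold assemblies with receptor genes
  planted as intact ORFs, pseudogenes (internal stop, frameshift, or
  conserved-window deletion), scaffold-end truncations, and splice-flanked
  exon-3 cassettes — coordinates, statuses, and boundaries all recorded.

* :func:`simulate_family` evolves a gene family along a species tree by a
  per-lineage linear birth-death process, emitting the surviving gene tree
  (full support) and per-branch event truth, including which events remain
  identifiable to parsimony reconciliation after extinct lineages are
  pruned.

All randomness flows from explicit seeds; fixed seeds give byte-identical
artifacts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio.Seq import Seq

from .assembly import GenomeAssembly
from .ogg import SpeciesTreeIndex

__all__ = [
    "PlantSpec",
    "FamilySimSpec",
    "PlantedLocus",
    "GenomeTruth",
    "FamilyTruth",
    "make_donor_cds",
    "plant_genome",
    "simulate_family",
    "evolve_sequences",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS: dict[str, list[str]] = {}
for _c in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
    _aa = str(Seq(_c).translate())
    _CODONS.setdefault(_aa, []).append(_c)

CONSERVED_WINDOW = "MFVSSGYATFSPLVF"  # 7TM-like conserved block in donors


# ------------------------------ donor proteins -----------------------------


def make_donor_cds(
    rng: np.random.Generator,
    length_aa: int = 300,
    window_start: int = 274,
    template: str | None = None,
    divergence: float = 0.0,
) -> str:
    """A synthetic receptor-like CDS: starts ATG, clean ORF, conserved window.

    With ``template`` given, point-mutates it at the requested amino-acid
    divergence (window and start preserved) instead of sampling fresh.
    """
    if template is None:
        prot = ["M"] + [rng.choice(list(_AA)) for _ in range(length_aa - 1)]
        prot[window_start - 1 : window_start - 1 + len(CONSERVED_WINDOW)] = list(
            CONSERVED_WINDOW
        )
    else:
        prot = list(template)
        protected = set(range(window_start - 1, window_start - 1 + len(CONSERVED_WINDOW)))
        protected.add(0)
        for i in range(len(prot)):
            if i not in protected and rng.random() < divergence:
                prot[i] = rng.choice([a for a in _AA if a != prot[i]])
    cds = "".join(rng.choice(_CODONS[aa]) for aa in prot)
    return cds + rng.choice(["TAA", "TAG", "TGA"])


# ------------------------------ genome planting ----------------------------


@dataclass
class PlantedLocus:
    locus_id: str
    family: str
    status: str  # intact | pseudogene | truncated | exon3
    mode: str  # clean | internal-stop | frameshift | window-deletion | 5prime | 3prime
    scaffold_id: str
    strand: str
    start: int  # CDS/exon interval, 0-based half-open, forward strand
    end: int
    protein: str
    acceptor: int | None = None  # exon3: forward-strand coord of exon start
    donor: int | None = None  # exon3: forward-strand coord of exon end


@dataclass
class GenomeTruth:
    seed: int
    loci: list[PlantedLocus]

    def by_status(self, status: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.status == status]


@dataclass
class PlantSpec:
    """What to plant: counts per category plus scaffold geometry."""

    family: str = "V1R"
    n_intact: int = 5
    n_pseudogene: int = 3
    n_truncated: int = 2
    n_exon3: int = 0
    pseudogene_modes: Sequence[str] = ("internal-stop", "frameshift", "window-deletion")
    scaffold_length: int = 12_000
    gc: float = 0.42
    seed: int = 0


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def plant_genome(
    spec: PlantSpec,
    donor_cds: Sequence[str] | None = None,
) -> tuple[GenomeAssembly, GenomeTruth]:
    """Build an assembly with planted receptor loci and a full truth table.

    One scaffold per planted locus (plus intergenic flanks) keeps plants
    non-overlapping by construction.  Intact and pseudogene plants sit in
    scaffold interiors behind an in-frame upstream stop codon so ORF
    extension recovers exactly the planted CDS; truncated plants are cut at
    a scaffold terminus; exon-3 plants are flanked by AG/GT splice
    dinucleotides with boundary coordinates recorded.
    """
    rng = np.random.default_rng(spec.seed)
    donors = list(donor_cds) if donor_cds else []
    n_needed = spec.n_intact + spec.n_pseudogene + spec.n_truncated + spec.n_exon3
    while len(donors) < n_needed:
        donors.append(make_donor_cds(rng))

    scaffolds: dict[str, str] = {}
    loci: list[PlantedLocus] = []
    counter = itertools.count(1)
    flank = max((spec.scaffold_length - 1000) // 2, 200)

    def add_interior(cassette: str, status: str, mode: str, protein: str,
                     cds_off: int, cds_len: int):
        """Place a cassette mid-scaffold on a random strand; record truth."""
        k = next(counter)
        name = f"scaf{k:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        left = _random_dna(rng, flank, spec.gc)
        right = _random_dna(rng, flank, spec.gc)
        if strand == "+":
            seq = left + cassette + right
            start = len(left) + cds_off
            end = start + cds_len
        else:
            seq = left + _revcomp(cassette) + right
            end = len(left) + len(cassette) - cds_off
            start = end - cds_len
        scaffolds[name] = seq
        loci.append(
            PlantedLocus(
                locus_id=f"{spec.family}-{status}-{k}",
                family=spec.family,
                status=status,
                mode=mode,
                scaffold_id=name,
                strand=strand,
                start=start,
                end=end,
                protein=protein,
            )
        )
        return name

    def protein_of(cds: str) -> str:
        p = str(Seq(cds).translate())
        return p[:-1] if p.endswith("*") else p

    di = 0
    for _ in range(spec.n_intact):
        cds = donors[di]
        di += 1
        cassette = "TAA" + cds  # in-frame stop bounds the upstream ATG walk
        add_interior(cassette, "intact", "clean", protein_of(cds), 3, len(cds))

    for i in range(spec.n_pseudogene):
        cds = donors[di]
        di += 1
        mode = spec.pseudogene_modes[i % len(spec.pseudogene_modes)]
        n_codons = len(cds) // 3
        mid = n_codons // 2
        if mode == "internal-stop":
            broken = cds[: mid * 3] + "TAA" + cds[mid * 3 + 3 :]
        elif mode == "frameshift":
            broken = cds[: mid * 3] + cds[mid * 3 + 1 :]  # single-nt deletion
        elif mode == "window-deletion":
            w0 = (274 - 1) * 3
            broken = cds[:w0] + cds[w0 + 3 * len(CONSERVED_WINDOW) :]
        else:
            raise ValueError(f"unknown pseudogene mode {mode!r}")
        cassette = "TAA" + broken
        add_interior(cassette, "pseudogene", mode, protein_of(cds), 3, len(broken))

    for i in range(spec.n_truncated):
        cds = donors[di]
        di += 1
        n_codons = len(cds) // 3
        keep = (n_codons * 2) // 3 * 3  # nt kept, in frame
        k = next(counter)
        name = f"scaf{k:03d}"
        if i % 2 == 0:  # 3' truncated: ORF runs off the scaffold end
            piece = "TAA" + cds[:keep]
            seq = _random_dna(rng, flank, spec.gc) + piece
            start, end = len(seq) - keep, len(seq)
            strand, mode = "+", "3prime"
        else:  # 5' truncated: reading enters from the scaffold start
            piece = cds[-(keep + 3) :]  # tail incl. stop, in frame at pos 0
            seq = piece + _random_dna(rng, flank, spec.gc)
            start, end = 0, keep + 3
            strand, mode = "+", "5prime"
        scaffolds[name] = seq
        loci.append(
            PlantedLocus(
                locus_id=f"{spec.family}-truncated-{k}",
                family=spec.family,
                status="truncated",
                mode=mode,
                scaffold_id=name,
                strand=strand,
                start=start,
                end=end,
                protein=str(Seq(seq[start:end]).translate()).strip("*"),
            )
        )

    for _ in range(spec.n_exon3):
        cds = donors[di]
        di += 1
        exon = cds[: len(cds) - 3]  # exon carries no stop codon
        k = next(counter)
        name = f"scaf{k:03d}"
        left = _random_dna(rng, flank, spec.gc)
        right = _random_dna(rng, flank, spec.gc)
        seq = left + "AG" + exon + "GT" + right
        start = len(left) + 2
        end = start + len(exon)
        scaffolds[name] = seq
        loci.append(
            PlantedLocus(
                locus_id=f"{spec.family}-exon3-{k}",
                family=spec.family,
                status="exon3",
                mode="clean",
                scaffold_id=name,
                strand="+",
                start=start,
                end=end,
                protein=str(Seq(exon).translate()),
                acceptor=start,
                donor=end,
            )
        )

    if not scaffolds:
        k = next(counter)
        scaffolds[f"scaf{k:03d}"] = _random_dna(rng, spec.scaffold_length, spec.gc)
    return GenomeAssembly(scaffolds), GenomeTruth(seed=spec.seed, loci=loci)


# --------------------------- birth-death families --------------------------


@dataclass
class FamilySimSpec:
    """Birth-death gene-family simulation along a known species tree.

    ``birth_rate``/``death_rate`` are per gene per unit branch time;
    ``branch_multipliers`` optionally scales both rates on named branches
    (keyed like :class:`~chemorep.ogg.SpeciesTreeIndex` branch ids), which
    is how correlated expansion/contraction regimes across families are
    simulated.
    """

    species_tree: str  # newick with branch lengths
    birth_rate: float = 0.1
    death_rate: float = 0.05
    n_root: int = 1
    seed: int = 0
    branch_multipliers: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_root < 1:
            raise ValueError("n_root must be >= 1")


@dataclass
class FamilyTruth:
    seed: int
    gains: dict[str, int]  # per species-tree branch (keyed by child node id)
    losses: dict[str, int]
    visible_gains: dict[str, int]  # events surviving lineage pruning
    visible_losses: dict[str, int]
    leaf_genes: dict[str, list[str]]
    identifiable: bool  # visible == true and all retained duplications LCA-consistent
    extinct: bool


class _GNode:
    __slots__ = ("children", "parent", "length", "label", "dup_branch", "sampled", "species")

    def __init__(self, parent=None):
        self.children: list[_GNode] = []
        self.parent = parent
        self.length = 0.0
        self.label: str | None = None
        self.dup_branch: str | None = None  # branch id where this node duplicated
        self.sampled = False
        self.species: str | None = None


def simulate_family(spec: FamilySimSpec) -> tuple[dendropy.Tree | None, FamilyTruth]:
    """Evolve ``n_root`` gene lineages along the species tree; emit truth.

    Within each species branch every gene lineage waits exponential times
    to duplicate (birth) or die; survivors are copied into both daughter
    branches at speciations.  The returned gene tree contains only lineages
    with sampled (extant-leaf) descendants, with true branch lengths,
    unifurcations suppressed, and full (100) support labels.  A family
    extinct in every species yields ``(None, truth)`` with
    ``truth.extinct`` set.
    """
    rng = np.random.default_rng(spec.seed)
    sp_tree = dendropy.Tree.get(data=spec.species_tree, schema="newick")
    sp = SpeciesTreeIndex(sp_tree)
    mults = dict(spec.branch_multipliers or {})
    gains: dict[str, int] = {b: 0 for b in sp.branch_ids()}
    losses: dict[str, int] = {b: 0 for b in sp.branch_ids()}
    leaf_genes: dict[str, list[str]] = {lf: [] for lf in sp.leaves}
    gene_counter = itertools.count(1)

    def branch_len(nid: str) -> float:
        node = sp.node_by_id[nid]
        return float(node.edge.length or 0.0)

    def evolve_on_branch(node: _GNode, t_left: float, branch: str) -> list[_GNode]:
        lam = spec.birth_rate * mults.get(branch, 1.0)
        mu = spec.death_rate * mults.get(branch, 1.0)
        total = lam + mu
        while True:
            dt = rng.exponential(1.0 / total) if total > 0 else math.inf
            if dt >= t_left:
                node.length += t_left
                return [node]
            node.length += dt
            t_left -= dt
            if rng.random() < lam / total:  # duplication
                gains[branch] += 1
                node.dup_branch = branch
                out: list[_GNode] = []
                for _ in range(2):
                    child = _GNode(parent=node)
                    node.children.append(child)
                    out.extend(evolve_on_branch(child, t_left, branch))
                return out
            losses[branch] += 1  # death
            return []

    def descend(node: _GNode, species_node_id: str):
        """Node has just arrived at species node; speciate or sample."""
        kids = sp.children.get(species_node_id, [])
        if not kids:
            gid = f"{species_node_id}|g{next(gene_counter)}"
            node.label = gid
            node.sampled = True
            node.species = species_node_id
            leaf_genes[species_node_id].append(gid)
            return
        for c in kids:
            child = _GNode(parent=node)
            node.children.append(child)
            survivors = evolve_on_branch(child, branch_len(c), c)
            for s in survivors:
                descend(s, c)

    roots = []
    for _ in range(spec.n_root):
        r = _GNode()
        descend(r, sp.root_id)
        roots.append(r)

    # mark sampled ancestry
    def mark(node: _GNode) -> bool:
        node.sampled = node.sampled or any([mark(c) for c in node.children])
        return node.sampled

    for r in roots:
        mark(r)

    # visible events: what survives pruning of extinct lineages
    visible_gains = {b: 0 for b in gains}
    visible_losses = {b: 0 for b in losses}
    lca_ok = True

    def species_of_gene(gid: str) -> str:
        return gid.split("|")[0]

    def sampled_leaf_species(node: _GNode) -> set[str]:
        if node.label is not None:
            return {species_of_gene(node.label)}
        out: set[str] = set()
        for c in node.children:
            if c.sampled:
                out |= sampled_leaf_species(c)
        return out

    def scan(node: _GNode, species_node_id: str, on_root_chain: bool):
        """Collect pruning-visible events.

        ``species_node_id`` is the species node at the bottom of the branch
        the node currently travels (duplication children stay on the same
        branch, so the context is invariant until the next speciation).
        ``on_root_chain`` marks nodes above the first retained speciation:
        there the gene-tree rooting is free, so a duplication is only
        safely recoverable when it is symmetric.
        """
        nonlocal lca_ok
        if not node.sampled:
            return
        if node.dup_branch is not None:
            a, b = node.children
            if a.sampled and b.sampled:
                # the duplication survives pruning; parsimony recovers it on
                # the right branch iff LCA mapping still calls it a
                # duplication there: the node must map to its true branch
                # and at least one child must map to the same node (both,
                # when the node sits on the freely-rootable root chain)
                visible_gains[node.dup_branch] += 1
                ma = sp.lca(sorted(sampled_leaf_species(a)))
                mb = sp.lca(sorted(sampled_leaf_species(b)))
                mapped = sp.lca([ma, mb])
                if mapped != node.dup_branch:
                    lca_ok = False
                elif on_root_chain:
                    if ma != mapped or mb != mapped:
                        lca_ok = False
                elif ma != mapped and mb != mapped:
                    lca_ok = False
            # one-sided survival: the duplication and the ensuing deaths
            # cancel out of the observable tree
            both = a.sampled and b.sampled
            for c in node.children:
                # a retained duplication is the first branching node of the
                # pruned tree, ending the freely-rootable chain
                scan(c, species_node_id, on_root_chain and not both)
        elif node.children:
            # speciation: an unsampled daughter copy is one visible loss,
            # charged at the top of that daughter branch (as parsimony does)
            kids = sp.children.get(species_node_id, [])
            sampled_kids = [c for c in node.children if c.sampled]
            for c_node, c_branch in zip(node.children, kids):
                if not c_node.sampled:
                    visible_losses[c_branch] += 1
                else:
                    # the root chain ends at the first speciation retained
                    # in the pruned tree (>= 2 sampled daughters)
                    scan(c_node, c_branch,
                         on_root_chain and len(sampled_kids) < 2)

    for r in roots:
        if r.sampled:
            scan(r, sp.root_id, True)

    extinct = all(len(v) == 0 for v in leaf_genes.values())
    identifiable = (
        not extinct
        and lca_ok
        and visible_gains == gains
        and visible_losses == losses
    )
    truth = FamilyTruth(
        seed=spec.seed,
        gains=gains,
        losses=losses,
        visible_gains=visible_gains,
        visible_losses=visible_losses,
        leaf_genes=leaf_genes,
        identifiable=identifiable,
        extinct=extinct,
    )
    if extinct:
        return None, truth

    # prune extinct lineages, suppress unifurcations, build a dendropy tree
    def prune(node: _GNode) -> _GNode | None:
        kept = [prune(c) for c in node.children if c.sampled]
        kept = [k for k in kept if k is not None]
        if node.label is not None:
            return node
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].length += node.length
            return kept[0]
        node.children = kept
        return node

    pruned = []
    for r in roots:
        if r.sampled:
            p = prune(r)
            if p is not None:
                pruned.append(p)
    if len(pruned) == 1:
        root = pruned[0]
    else:
        root = _GNode()
        root.children = pruned

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(gnode: _GNode, dnode: dendropy.Node):
        dnode.edge.length = gnode.length
        if gnode.label is not None:
            dnode.taxon = taxa.require_taxon(label=gnode.label)
            return
        dnode.label = "100"  # simulated trees are fully supported
        for c in gnode.children:
            child = dendropy.Node()
            dnode.add_child(child)
            build(c, child)

    build(root, tree.seed_node)
    tree.seed_node.label = None
    return tree, truth


# ---------------------------- sequence evolution ---------------------------


def evolve_sequences(
    gene_tree: dendropy.Tree,
    root_cds: str,
    rate: float,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a root CDS along a gene tree, keeping every descendant intact.

    Substitutions are proposed at Poisson(rate x branch-length x codons)
    events per branch; proposals creating an internal stop or destroying
    the initiation codon are rejected, so leaves always translate cleanly.
    Returns leaf label -> CDS.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    p = str(Seq(root_cds).translate())
    if not p.endswith("*") or "*" in p[:-1] or not p.startswith("M"):
        raise ValueError("root_cds must be a clean ORF (M ... stop)")
    rng = np.random.default_rng(seed)
    n_codons = len(root_cds) // 3 - 1  # mutable codons exclude the stop
    out: dict[str, str] = {}

    def walk(node, cds: str):
        bl = float(node.edge.length or 0.0)
        n_events = rng.poisson(rate * bl * n_codons)
        s = list(cds)
        for _ in range(n_events):
            for _try in range(20):
                ci = int(rng.integers(1, n_codons))  # keep the ATG
                pos = int(rng.integers(0, 3))
                old = s[ci * 3 + pos]
                new = rng.choice([b for b in "ACGT" if b != old])
                s[ci * 3 + pos] = new
                codon = "".join(s[ci * 3 : ci * 3 + 3])
                if codon in ("TAA", "TAG", "TGA"):
                    s[ci * 3 + pos] = old  # reject: would create a stop
                    continue
                break
        cds2 = "".join(s)
        if node.is_leaf():
            out[node.taxon.label] = cds2
        for c in node.child_nodes():
            walk(c, cds2)

    walk(gene_tree.seed_node, root_cds)
    return out
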