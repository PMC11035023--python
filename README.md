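# chemorep

Chemosensory receptor gene families — odorant receptors (OR), vomeronasal
receptors type 1 and 2 (V1R, V2R), and taste receptors (T1R, T2R) — are
among the largest and most volatile gene families in mammalian genomes,
expanding and contracting rapidly as species' ecology changes. `chemorep`
is a toolkit for mining these families from draft genome assemblies,
classifying each locus, grouping genes into orthologous gene groups
(OGGs), counting per-branch gene gains and losses on a species phylogeny,
and testing whether different families expanded and contracted in
synchrony. It is aimed at comparative genomicists studying multigene
family evolution.

## What it computes

* **Assembly statistics and the truncation model.** For a gene of genomic
  span `L` placed uniformly on an assembly of scaffolds, the probability
  that scaffold ends cut the gene is `P = (n1·L + Σ Si)/N`, with `n1` the
  number of scaffolds longer than `L`, `Si` the lengths of the shorter
  scaffolds, and `N` the total assembly length. This quantifies why
  multi-exon receptor genes (~25.3 kb) are annotated through their large
  exon 3 rather than full CDSs.
* **Best-hit mining.** Translated-search hits are merged per locus
  (same-scaffold, same-strand overlap closure) and each locus is labelled
  with the query of lowest e-value (cutoff 1e-20).
* **Intronless annotation (OR/V1R/T2R).** ORF extension from each region;
  anchored initiation-codon selection (most upstream ATG within −40..0 of
  the V1R anchor, −27..0 for T2R); a conserved 7TM-window gap filter
  (≥ 7 gaps ⇒ pseudogene); classification into intact / truncated (runs
  off a contig end) / pseudogene, plus four deduplication filters.
* **Exon-3 annotation (V2R/T1R).** Length/stop/frameshift screening, exon
  boundary refinement under the GT-AG splice rule (±15 nt), and clade
  assignment against reference trees.
* **Phylogenetics.** Neighbor-joining trees from Poisson-correction
  distances `d = −ln(1 − p)`, with column-resampling bootstrap supports.
* **OGGs and gain/loss counting.** Bootstrap-thresholded (>70) clade
  decomposition into OGGs, then duplication–loss parsimony reconciliation
  of each OGG's gene tree against the species tree (exhaustive rooting, no
  outgroup), yielding per-branch gains, losses, ancestral counts, and
  per-gene rates.
* **Comparative statistics.** Repertoire tables (means, coefficients of
  variation), per-OGG dispersion F tests, Spearman correlations of
  per-branch gains/losses between families, and phylogenetically
  independent contrasts.
* **Synthetic data.** Planted genomes (intact/pseudogene/truncated/exon-3
  loci with recorded truth) and birth–death gene-family simulation along a
  species tree with per-branch event truth — every pipeline stage is
  testable end to end without real assemblies.

## Worked example

Mine a synthetic genome with planted receptor genes and recover them:

```python
import numpy as np
from chemorep import (PlantSpec, plant_genome, make_donor_cds,
                      annotate_intronless, V1R_PROFILE,
                      truncation_probability)

rng = np.random.default_rng(7)
donors = [make_donor_cds(rng, template=V1R_PROFILE.reference_seq,
                         divergence=0.1) for _ in range(10)]
assembly, truth = plant_genome(
    PlantSpec(seed=3, n_intact=5, n_pseudogene=3, n_truncated=2), donors)

calls = annotate_intronless(
    assembly, {V1R_PROFILE.reference_id: V1R_PROFILE.reference_seq},
    "V1R", profile=V1R_PROFILE)
counts = {s: sum(c.status == s for c in calls)
          for s in ("intact", "truncated", "pseudogene")}
print(counts)

est = truncation_probability(assembly, L=25_300)
print(f"P(truncation) = {est.P:.3f}  (n1={est.n1}, N={est.N})")
```

Output:

```
{'intact': 5, 'truncated': 2, 'pseudogene': 3}
P(truncation) = 1.000  (n1=0, N=107408)
```

The annotator recovers exactly the planted 5 intact / 2 truncated /
3 pseudogene loci (the intact calls match the planted coordinates base
for base), and the truncation model reports `P = 1` because every
scaffold in this small fixture is shorter than a 25.3 kb gene span — on
such an assembly no multi-exon gene could be recovered intact, which is
the motivation for exon-3-based annotation.

Count gains and losses of a simulated family:

```python
from chemorep import FamilySimSpec, simulate_family, reconcile_counts, read_newick

sp = "((A:1.0,B:1.0)AB:1.0,(C:1.0,D:1.0)CD:1.0)R;"
tree, truth = simulate_family(FamilySimSpec(species_tree=sp,
                                            birth_rate=0.15,
                                            death_rate=0.08, seed=11))
table = reconcile_counts(tree, read_newick(sp))
print("gains ", {b: g for b, g in table.gains.items() if g})
print("losses", {b: l for b, l in table.losses.items() if l})
print("truth ", {b: g for b, g in truth.gains.items() if g},
      {b: l for b, l in truth.losses.items() if l})
```

Output:

```
gains  {'AB': 1, 'B': 1}
losses {'A': 1, 'C': 1}
truth  {'AB': 1, 'B': 1} {'A': 1, 'C': 1}
```

The reconciliation recovers the simulated history exactly: duplications
on the branches to the A/B ancestor and to species B, with one copy lost
in A and the family lost in C.

A thin CLI covers the file-level entry points:
`chemorep assembly-stats`, `chemorep trunc-prob`, `chemorep besthit`,
`chemorep njtree`, and `chemorep simulate genome|family`.

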