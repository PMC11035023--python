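# Methods

This note documents the models, procedures, and design choices behind
`chemorep`: a pipeline for mining chemosensory G protein–coupled receptor
gene families (odorant receptors OR, vomeronasal receptors V1R/V2R, taste
receptors T1R/T2R) from draft genome assemblies and analysing their
evolutionary gains and losses across a species phylogeny.

## Assembly model and the truncation probability

A draft assembly is a set of scaffolds. A gene whose genomic span
(initiation codon to stop codon, introns included) is `L` bp cannot be
recovered intact from any scaffold of length ≤ `L`; on a longer scaffold
it is cut whenever its midpoint falls within `L/2` of either end. With the
gene midpoint placed uniformly over the concatenated assembly of total
length `N`, the truncation probability is

    P = (n1·L + Σ Si) / N

where `n1` counts scaffolds longer than `L` and the sum runs over the
lengths `Si` of the scaffolds of length ≤ `L`. Scaffolds exactly `L` long
count as short; `N` includes every scaffold (no length cutoff). The closed
form is validated against a Monte-Carlo midpoint-placement sampler
(`truncation_probability_mc`), which agrees within binomial 3σ by
construction of the geometry. The default `L` = 25,300 bp is the mean
genomic span of mouse V2R genes; it is exposed as a parameter because the
exact treatment of UTR-containing exons in that average is not fixed.

Assembly summary statistics (N50, GC over unambiguous bases, totals above
a length cutoff, default 1,000 bp) follow the standard definitions.

## Best-hit regions

Translated homology hits (external 12-column tabular output, e-value
cutoff 1e-20 applied at parse time; coordinates normalised to 0-based
half-open forward-strand intervals) are reduced to one region per locus: a
"genomic region" is the transitive overlap closure of hits on the same
scaffold and strand (a `merge_gap` option joins near-adjacent hits, needed
when a frameshift splits one locus into two abutting hits). Each region
takes the query with the lowest e-value there, ties broken by higher
bitscore and then lexicographic query id. E-values are opaque ranking
keys; the package never recomputes search statistics. A built-in naive
seed-and-extend translated search over six-frame translations supplies
hits for fixtures and round-trip tests; production runs ingest external
tabular hits.

## Intronless annotation (OR/V1R/T2R)

Each best-hit region is extended in frame on its coding strand: downstream
to the first stop codon, upstream to the farthest ATG not preceded
(in-frame, after an intervening stop) by a stop codon. Evidence is
collected along the way: internal stops inside the hit span, frame
conflicts among member hits (frameshifts), and walks that fall off the
scaffold (contig ends). Classification is exhaustive:

* **intact** — complete ORF (M … stop), no disruption, passes the length
  gates (250 aa at the candidate stage, 280 aa after alignment);
* **truncated** — the open reading runs to a scaffold terminus with no
  disruption in the covered span;
* **pseudogene** — everything else (internal stop, frameshift, conserved
  window gaps, or too short), matching the convention that every best hit
  that is neither intact nor truncated is a pseudogene.

Family profiles anchor two alignment-based refinements. The initiation
codon is chosen as the most upstream M within a window upstream of a
conserved anchor residue (V1R: positions −40..0 of the residue
corresponding to mouse Vmn1r1 residue 24, a conserved G; T2R: −27..0 of
the residue corresponding to human TAS2R5 residue 16, a conserved E);
candidates whose N-terminal portion has zero length, or with no start in
the window, are removed. Candidates with ≥ 7 gap characters across the
15-column 7th-transmembrane-helix block (the `MFVSSGYATFSPLVF` region of
the V1R reference) are removed as conserved-region-disrupted pseudogenes.
Profile alignments are produced by a pluggable aligner; the built-in
backend aligns each candidate pairwise to the family reference and merges
insertions (center-star), which is sufficient for anchor location and
window gap counting and keeps results independent of external aligner
versions. The shipped reference proteins are synthetic consensus-like
receptor sequences carrying the conserved window — constructed fixtures,
not database extracts.

Four refinement filters then deduplicate assembly artifacts, in order:
(i) calls on contigs < 1 kb are dropped; (ii) when one contig is embedded
in a longer one (≥ 99% nucleotide identity over ≥ 95% of the shorter; the
coverage fraction is our choice) and the proteins are > 99% identical, the
call on the shorter contig is dropped; (iii) exact amino-acid duplicates
among intact/truncated calls are dropped (truncated contained in intact →
drop truncated; nested truncated → drop the shorter); (iv) an
N-terminus-missing and a C-terminus-missing truncated pair whose overlap
is 100% identical and ungapped are combined into one intact call (overlap
≥ 1 aa; each merge reduces the call count by exactly 1). Every removal and
merge is logged with its rule id.

Pairwise protein identity is matches / alignment columns with terminal
gaps excluded, on a global alignment. Identity clustering (80% for query
thinning, 90% for repertoire-diversity summaries) is single linkage, with
the longest member (ties: lexicographic id) as representative. Codons
containing ambiguous bases translate to X and are not disruptions, but a
run of ≥ 5 consecutive X marks a pseudogene.

## Exon-3 annotation (V2R/T1R)

Multi-exon receptor genes are annotated through their large ligand-binding
"exon 3" (~810 bp, ~270 aa) instead of full CDSs, because full spans are
frequently cut by scaffold ends (see the truncation model). A best-hit
region passes to the intact track when its translation is ≥ 250 aa with no
interrupting stop or frameshift. Its ends are then snapped to canonical
splice boundaries — the genomic dinucleotide immediately 5′ of the exon
must be AG (intron end) and immediately 3′ must be GT (intron start) —
searching ±15 nt of each hit end on the coding strand. Noncanonical splice
sites are rejected outright. Where several in-window positions satisfy
GT-AG, the pair maximising identity of the re-translated exon to the
reference exon-3 protein wins, ties going to the positions nearest the
original hit ends; this deterministic rule replaces manual inspection.
Candidates with no valid boundary pair are discarded; failed candidates on
contigs ≥ 1 kb are exon-3 pseudogenes. Intact calls are assigned to
receptor clades (V2R: AH, A1-5, A8, A10, B, C, D; T1R: T1R1/2/3) by the
smallest surrounding clade of a reference tree containing references of a
single clade; candidates grouping with non-receptor references (e.g.
calcium-sensing-receptor-like sequences) are excluded from the family.

## Distance trees and supports

Protein distances use the Poisson correction `d = −ln(1 − p)` with `p` the
mismatch proportion over pairwise-deleted columns (both sequences
ungapped). A saturated pair (`p = 1`) raises an error rather than being
clamped — silent saturation corrupts the tree. Trees are built by
canonical neighbor joining (Q-criterion); a negative branch length is
clamped to zero with the deficit moved to its sibling edge, and taxa are
processed in sorted order so results are independent of input order.
Bootstrap supports are the percentage of column-resampled replicates
(default 500) containing each internal bipartition of the point-estimate
tree, written as internal node labels — the common Newick dialect, so
externally built trees with supports can be used anywhere these trees are
consumed.

## Orthologous gene groups

An OGG is the set of genes descended from one gene in the species' most
recent common ancestor. Ingroup genes are first attached to reference OGGs
via the winning query of their best-hit region. Each reference OGG's gene
tree (ingroup plus reference genes) is then decomposed: if the ingroup is
monophyletic it is one OGG; otherwise clades with bootstrap support
strictly above 70 containing part (not all) of the remaining ingroup are
extracted iteratively when they either (i) also contain reference genes,
or (ii) consist only of ingroup genes but are separated from the rest of
the ingroup by reference lineages. Candidate clades are subtrees of the
reference-rooted tree whose bipartition is non-trivial in the unrooted
sense; extraction removes the whole clade and proceeds largest-first with
lexicographic tie-breaks, and the leftover ingroup forms the final OGG.
A candidate OGG splits in two when its ingroup-only tree divides, with
support above threshold, into two clades that each contain genes of the
designated basal species and of other species.

## Gain/loss counting by reconciliation

Per OGG, the gene tree is reconciled against the binary species tree.
Edges with bootstrap support ≤ 70 are collapsed to polytomies ("> 70" is
the retention condition). Because no outgroup is used per OGG, the rooting
is chosen exhaustively over all edges of the unrooted gene tree to
minimise duplications + losses; polytomies are resolved by exhaustive
search over binary resolutions (raising an error beyond ~6-child
polytomies rather than approximating), with ties broken toward fewer
duplications and then deterministically. Under LCA mapping, a gene node
mapped to the same species node as one of its children is a duplication,
charged as a gain to the branch leading into that node (the root node's
stem for root-mapped duplications); a lineage passing a speciation with no
descendants on one side is a loss charged to that side's branch, and an
OGG whose root mapping lies below the species root is charged losses along
the stem path. The conservation identity — root count + gains − losses
along any root-to-leaf path equals the observed per-species count — is
asserted on every call. The implementation is checked against an
independent brute-force embedding oracle on random gene trees.

Per-gene rates divide each branch's pooled events by the pooled gene count
at the ancestral node the branch connects to; the family rate is the
arithmetic mean over branches with a nonzero ancestral count.

## Comparative statistics

Repertoire summaries use sample (n−1) variances; the coefficient of
variation is sample SD / mean. Dispersion between families' per-OGG counts
uses the variance-ratio F test with a two-sided p-value
`2·min(P[F≤f], P[F≥f])`. Per-branch gain/loss counts are correlated
between families by Spearman's rank correlation with average ranks
(exact permutation p-values below 10 observations, the t approximation
with n−2 df otherwise); branches are treated as independent observations
because each branch's events are estimated separately through the OGGs.
No multiple-testing correction is applied across family pairs (per-pair
significance is reported as in the source analyses). Cross-species trait
correlations use Felsenstein's phylogenetically independent contrasts
(pruning recursion; contrast correlations computed through the origin);
polytomies are rejected by default and can be resolved with zero-length
edges only on request.

## Synthetic data: what it emulates and what it does not

The generator provides every input with known truth.

**Planted genomes.** Scaffolds of random intergenic sequence at a chosen
GC fraction (default 0.42) carry donor receptor CDSs — synthetic
consensus-derived ORFs with the conserved 7TM window — planted as: intact
interior genes behind an in-frame upstream stop (so ORF extension recovers
exactly the planted interval); pseudogenes disrupted by an internal stop,
a single-nucleotide deletion (frameshift), or an in-frame deletion of the
conserved window; truncations cut at a scaffold terminus on the 5′ or 3′
side; and exon-3 cassettes flanked by AG/GT with recorded boundaries. One
scaffold per locus guarantees non-overlap. What this does not emulate:
repeats, segmental duplications, gene conversion, assembly gaps inside
genes, and base-calling error — so round-trip perfection on these fixtures
demonstrates the correctness of the annotation logic, not its robustness
to real assembly noise.

**Birth–death families.** Along a known species tree, each gene lineage
duplicates at rate λ and dies at rate μ per unit branch length
(exponential waiting times; multiple events per branch allowed; optional
per-branch rate multipliers). Survivor gene trees carry true branch
lengths and full (100) supports; the truth table records every event by
branch. Events are additionally classified as parsimony-identifiable: a
duplication surviving pruning is identifiable when LCA mapping still calls
it a duplication on its true branch (both children must map there when the
duplication sits on the freely-rootable chain above the first retained
branching node), and a loss is identifiable when it removes a whole
daughter copy at the top of its branch with the parent lineage retained.
Replicates where some events cancel (e.g. a duplication whose copy dies on
the same branch, or deaths deep inside an unsampled subtree) are flagged
non-identifiable; there, parsimony necessarily infers no more than the
simulated totals (the bound is tested, not assumed). Sequence evolution
along gene trees is codon-preserving (proposals creating stops or
destroying the start are rejected), so donors remain valid ORFs while
identity decays with path length.

**Synchrony experiment.** Two families are simulated along an 8-species
balanced tree (14 branches), each as 12 OGGs, with per-branch rate
multipliers `exp(U(−2, 2))` either shared between families (correlated
regime) or drawn independently (null regime); base rates are λ = 0.3,
μ = 0.18 per unit time. Inferred per-branch gains/losses (pooled over
OGGs after reconciliation) are correlated between families. These sizes
were chosen so that shared drivers produce a clearly detectable rank
correlation (pilot mean r ≈ 0.7 for gains) while a replicate remains
cheap; the null regime's false-positive rate at the 5% threshold is
checked against the binomial 3σ band.

## Numerical and policy choices

* Coordinates are 0-based half-open internally; strand-sensitive
  operations convert to the coding strand first.
* All tie-breaks are lexicographic or index-ordered; the pipeline has no
  hidden randomness, and every stochastic component takes an explicit
  seed.
* Exact protein-identity filters use string equality; thresholded
  identities use the global-alignment definition above.
* Problem sizes in the test-suite and acceptance script (20 randomized
  assemblies at 10^6 Monte-Carlo draws; 300–500 random gene trees of ≤ 8
  leaves; 300 birth–death replicates for event recovery and 1,000 for the
  leaf-count expectation; 200 replicates per synchrony regime) were chosen
  as the smallest sizes at which the binomial/SE tolerances stated with
  each check are informative.

## Known limitations

* The OR family reuses the generic intronless pipeline with OR-specific
  profile parameters; the length gates default to the V1R/T2R values and
  OR conserved windows must be supplied as configuration.
* Exon-3 phase is configurable but defaults to phase 0; genes whose exon 3
  starts mid-codon need the phase set explicitly.
* Reconciliation ties between equally parsimonious rootings are resolved
  deterministically, which may differ from other implementations' corner
  cases; divergences are confined to ties.
* The decomposition procedure evaluates clades of the tree as rooted;
  trees should be rooted sensibly (references basal), as is natural for
  reference-anchored gene trees.
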