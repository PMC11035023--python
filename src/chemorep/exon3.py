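"""Exon-3 annotation for multi-exon receptor genes (V2R/T1R).

Full-length V2R/T1R coding sequences span 6-7 exons over tens of kilobases
and are routinely cut by scaffold ends, so the pipeline annotates the large
ligand-binding "exon 3" (~810 bp) as a proxy for the gene.  A best-hit
region is kept on the intact track when its translation is at least 250
residues with no interrupting stop or frameshift; its ends are then snapped
to canonical splice boundaries (intron ends with AG immediately 5' of the
exon, intron begins with GT immediately 3') within a small window, and the
call is assigned to a receptor clade by its position in a reference tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .assembly import GenomeAssembly
from .hits import BestHitRegion
from .intronless import STOPS, pairwise_identity

__all__ = ["Exon3Call", "call_exon3", "refine_gtag_boundaries", "assign_clade"]


@dataclass
class Exon3Call:
    """One exon-3 locus: coordinates, splice boundaries, status, clade."""

    call_id: str
    family: str  # V2R | T1R (category of the winning query)
    status: str  # intact | pseudogene | discarded | candidate
    scaffold_id: str
    strand: str
    start: int  # exon interval, 0-based half-open, forward strand
    end: int
    protein: str
    acceptor_ok: bool = False  # AG immediately 5' (coding strand)
    donor_ok: bool = False  # GT immediately 3' (coding strand)
    clade: str | None = None
    evidence: list[str] = field(default_factory=list)


def _coding(seq: str, strand: str) -> str:
    return seq if strand == "+" else str(Seq(seq).reverse_complement())


def call_exon3(
    region: BestHitRegion,
    assembly: GenomeAssembly,
    min_aa: int = 250,
    call_id: str | None = None,
) -> Exon3Call:
    """Screen a best-hit region for the intact exon-3 track.

    Translations shorter than ``min_aa``, or containing an interrupting
    stop codon, or from frame-conflicting (frameshifted) hit regions go to
    the pseudogene track; survivors proceed to boundary refinement.
    """
    seq = assembly.scaffolds.get(region.scaffold_id)
    if seq is None:
        raise ValueError(f"unknown scaffold {region.scaffold_id!r}")
    if region.start < 0 or region.end > len(seq):
        raise ValueError(
            f"region [{region.start}, {region.end}) outside scaffold {region.scaffold_id!r}"
        )
    L = len(seq)
    cseq = _coding(seq, region.strand)
    if region.strand == "+":
        c_start, c_end = region.start, region.end
    else:
        c_start, c_end = L - region.end, L - region.start

    evidence: list[str] = []
    frames = {abs(f) - 1 for f in region.frames if f != 0 and ((f > 0) == (region.strand == "+"))}
    if len(frames) > 1:
        evidence.append("frameshift")
    span = cseq[c_start : c_start + (c_end - c_start) // 3 * 3]
    protein = str(Seq(span).translate()) if span else ""
    if "*" in protein:
        evidence.append("internal-stop")
    if len(protein) < min_aa:
        evidence.append(f"short<{min_aa}aa")
    status = "candidate" if not evidence else "pseudogene"
    return Exon3Call(
        call_id=call_id or f"{region.scaffold_id}:{region.start}-{region.end}({region.strand})",
        family=region.category,
        status=status,
        scaffold_id=region.scaffold_id,
        strand=region.strand,
        start=region.start,
        end=region.end,
        protein=protein,
        evidence=evidence,
    )


def refine_gtag_boundaries(
    candidate: Exon3Call,
    assembly: GenomeAssembly,
    window_nt: int = 15,
    reference_protein: str | None = None,
) -> Exon3Call:
    """Snap the exon ends to GT-AG splice boundaries within ``window_nt``.

    Valid 5' positions have the genomic dinucleotide AG immediately
    upstream (the intron's last two bases); valid 3' positions have GT
    immediately downstream (the intron's first two).  All checks are on the
    coding strand.  Among valid pairs that keep the exon length a multiple
    of 3 and its translation clean, the pair maximizing identity to
    ``reference_protein`` wins (ties: nearest to the original hit ends).
    With no valid pair the candidate is discarded.  Noncanonical splice
    sites are never accepted.
    """
    if candidate.status != "candidate":
        return candidate
    seq = assembly.scaffolds[candidate.scaffold_id]
    L = len(seq)
    cseq = _coding(seq, candidate.strand)
    if candidate.strand == "+":
        c_start, c_end = candidate.start, candidate.end
    else:
        c_start, c_end = L - candidate.end, L - candidate.start

    starts = [
        p
        for p in range(max(2, c_start - window_nt), min(L, c_start + window_nt) + 1)
        if cseq[p - 2 : p] == "AG"
    ]
    ends = [
        p
        for p in range(max(0, c_end - window_nt), min(L - 2, c_end + window_nt) + 1)
        if cseq[p : p + 2] == "GT"
    ]
    best = None  # (score, |shift5|+|shift3|, s, e, protein)
    for s in starts:
        for e in ends:
            if e <= s or (e - s) % 3 != 0:
                continue
            prot = str(Seq(cseq[s:e]).translate())
            if "*" in prot:
                continue
            score = (
                pairwise_identity(prot, reference_protein)
                if reference_protein
                else 0.0
            )
            tie = abs(s - c_start) + abs(e - c_end)
            key = (-score, tie, s, e)
            if best is None or key < best[0]:
                best = (key, s, e, prot)
    if best is None:
        return replace(candidate, status="discarded", evidence=candidate.evidence + ["no-gtag-boundary"])
    _, s, e, prot = best
    if candidate.strand == "+":
        f_start, f_end = s, e
    else:
        f_start, f_end = L - e, L - s
    return replace(
        candidate,
        status="intact",
        start=f_start,
        end=f_end,
        protein=prot,
        acceptor_ok=True,
        donor_ok=True,
    )


def assign_clade(
    calls: Sequence[Exon3Call],
    tree,
    reference_clades: Mapping[str, str],
    reject_clades: Sequence[str] = ("CaSR",),
) -> list[Exon3Call]:
    """Label intact calls with the receptor clade they nest inside.

    ``tree`` is a dendropy tree whose leaves include the call ids and the
    reference exon-3 sequences; ``reference_clades`` maps reference leaf
    labels to clade names (AH, A1-5, A8, A10, B, C, D for V2R; T1R1/2/3).
    Each call takes the clade of the smallest surrounding clade that
    contains references of exactly one clade; calls landing with rejected
    (non-receptor, e.g. calcium-sensing receptor-like) references are
    dropped from the receptor set; otherwise they are "unassigned".
    """
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    out = []
    for call in calls:
        if call.status != "intact":
            out.append(call)
            continue
        node = leaf_by_label.get(call.call_id)
        if node is None:
            raise ValueError(f"call {call.call_id!r} absent from tree")
        clade = None
        cur = node.parent_node
        while cur is not None:
            labels = {
                reference_clades[lf.taxon.label]
                for lf in cur.leaf_iter()
                if lf.taxon.label in reference_clades
            }
            if labels:
                if len(labels) == 1:
                    clade = labels.pop()
                break
            cur = cur.parent_node
        if clade in reject_clades:
            out.append(replace(call, status="discarded", clade=clade,
                               evidence=call.evidence + ["non-receptor-clade"]))
        else:
            out.append(replace(call, clade=clade if clade else "unassigned"))
    return out
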