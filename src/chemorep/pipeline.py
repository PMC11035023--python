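"""End-to-end annotation pipelines built from the module operations.

These are the orchestration entry points a user (and the round-trip tests)
call: search a genome with family queries, reduce hits to best-hit
regions, extend/refine/classify, and apply the refinement filters.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .assembly import GenomeAssembly
from .exon3 import Exon3Call, call_exon3, refine_gtag_boundaries
from .hits import HitRecord, merge_and_best_hit, naive_translated_search
from .intronless import (
    FamilyProfile,
    GeneCall,
    apply_dedup_filters,
    build_profile_msa,
    classify_call,
    conserved_window_gap_filter,
    extend_orf,
    select_initiation_codon,
)

__all__ = ["annotate_intronless", "annotate_exon3"]


def annotate_intronless(
    assembly: GenomeAssembly,
    queries: Mapping[str, str],
    family: str,
    profile: FamilyProfile | None = None,
    hits: Sequence[HitRecord] | None = None,
    merge_gap: int = 30,
    min_cds_aa: int = 250,
    dedup: bool = False,
    min_contig_bp: int = 1000,
) -> list[GeneCall]:
    """Mine one intronless family (OR/V1R/T2R) from an assembly.

    With ``hits`` omitted, the built-in naive translated search supplies
    them (fixture/round-trip use; production runs ingest external tabular
    hits).  ``profile`` enables the anchored initiation-codon selection and
    conserved-window gap filter; candidates failing them are demoted to
    pseudogenes (no-start candidates to discarded), mirroring the rule
    that every non-intact, non-truncated best hit is a pseudogene.
    """
    if hits is None:
        hits = naive_translated_search(queries, assembly)
    category_map = {q: family for q in queries}
    regions = merge_and_best_hit(hits, category_map, merge_gap=merge_gap)
    calls: list[GeneCall] = []
    for i, region in enumerate(regions):
        cand = extend_orf(region, assembly, family=family, min_cds_aa=min_cds_aa,
                          call_id=f"{family}-{i + 1:04d}")
        calls.append(classify_call(cand, min_cds_aa=min_cds_aa))

    if profile is not None:
        intact = {c.call_id: c for c in calls if c.status == "intact"}
        if intact:
            msa = build_profile_msa({k: v.protein for k, v in intact.items()}, profile)
            chosen = select_initiation_codon(msa, profile)
            for cid, call in intact.items():
                if cid not in chosen:
                    call.status = "pseudogene"
                    call.evidence.append("no-start-in-window")
                    continue
                prot, trim = chosen[cid]
                if trim:
                    call.protein = prot
                    if call.strand == "+":
                        call.start += 3 * trim
                    else:
                        call.end -= 3 * trim
            survivors = {
                cid: c for cid, c in intact.items() if c.status == "intact"
            }
            if survivors:
                msa2 = build_profile_msa(
                    {k: v.protein for k, v in survivors.items()}, profile
                )
                keep = set(conserved_window_gap_filter(msa2, profile))
                for cid, call in survivors.items():
                    if cid not in keep:
                        call.status = "pseudogene"
                        call.evidence.append("conserved-window-gaps")

    if dedup:
        calls, _ = apply_dedup_filters(calls, assembly, min_contig_bp=min_contig_bp)
    return calls


def annotate_exon3(
    assembly: GenomeAssembly,
    queries: Mapping[str, str],
    family: str,
    hits: Sequence[HitRecord] | None = None,
    merge_gap: int = 30,
    min_aa: int = 250,
    window_nt: int = 15,
    min_contig_bp: int = 1000,
) -> list[Exon3Call]:
    """Mine exon-3 loci of a multi-exon family (V2R/T1R) from an assembly.

    Candidates passing the length/stop/frameshift screen have their ends
    snapped to AG/GT splice boundaries (scored against the winning query);
    failures on contigs of at least ``min_contig_bp`` are pseudogenes,
    shorter-contig failures are discarded.
    """
    if hits is None:
        hits = naive_translated_search(queries, assembly)
    category_map = {q: family for q in queries}
    regions = merge_and_best_hit(hits, category_map, merge_gap=merge_gap)
    lengths = assembly.lengths
    out: list[Exon3Call] = []
    for i, region in enumerate(regions):
        cand = call_exon3(region, assembly, min_aa=min_aa,
                          call_id=f"{family}-e3-{i + 1:04d}")
        if cand.status == "candidate":
            cand = refine_gtag_boundaries(
                cand,
                assembly,
                window_nt=window_nt,
                reference_protein=queries.get(region.query_id),
            )
        if cand.status in ("pseudogene", "discarded"):
            if lengths[cand.scaffold_id] >= min_contig_bp:
                cand.status = "pseudogene"
            else:
                cand.status = "discarded"
        out.append(cand)
    return out
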