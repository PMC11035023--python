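"""Annotation of intronless receptor genes (OR/V1R/T2R) from best-hit regions.

Each best-hit region is extended along the genome to the longest open
reading frame (initiation codon to stop codon) and classified as

* ``intact``      — complete ORF, no disruptions, passes the family gates;
* ``truncated``   — the open reading runs off a scaffold end with no
                    disruption in the covered span (could be intact in a
                    better assembly);
* ``pseudogene``  — carries internal stops, frameshifts, or gaps in the
                    family's conserved window.

Family-specific refinement uses a profile: an anchored initiation-codon
window (e.g. ATG chosen at the most upstream position within -40..0 of the
anchor residue for vomeronasal type-1 receptors, -27..0 for bitter taste
receptors), a conserved 7th-transmembrane-helix window whose gap count
flags pseudogenes, and minimum length gates (250 aa for candidate CDSs,
280 aa after alignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .assembly import GenomeAssembly
from .hits import BestHitRegion

__all__ = [
    "GeneCall",
    "FamilyProfile",
    "extend_orf",
    "select_initiation_codon",
    "conserved_window_gap_filter",
    "classify_call",
    "apply_dedup_filters",
    "identity_cluster",
    "pairwise_identity",
    "build_profile_msa",
    "V1R_PROFILE",
    "T2R_PROFILE",
]

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneCall:
    """One mined receptor locus with status and disruption evidence."""

    call_id: str
    family: str
    status: str  # intact | truncated | pseudogene | discarded | candidate
    scaffold_id: str
    strand: str
    start: int  # CDS interval, 0-based half-open, forward strand
    end: int
    protein: str
    evidence: list[str] = field(default_factory=list)

    @property
    def has_disruption(self) -> bool:
        return any(
            e.startswith(("internal-stop", "frameshift", "conserved-window-gaps", "long-x-run"))
            for e in self.evidence
        )

    @property
    def contig_end_sides(self) -> set[str]:
        return {e.split("-")[-1] for e in self.evidence if e.startswith("contig-end")}


@dataclass(frozen=True)
class FamilyProfile:
    """Family-specific parameters for intronless annotation.

    ``anchor_index`` is the 1-based residue index of the anchor in the
    reference protein (e.g. residue 24 of mouse Vmn1r1, a conserved G);
    ``atg_window`` w means initiation codons are sought at positions
    -w..0 relative to the anchor.  ``conserved_window_span`` is the 1-based
    inclusive residue span of the conserved block in the reference.
    """

    family: str
    reference_id: str
    reference_seq: str
    anchor_index: int
    atg_window: int
    conserved_window_span: tuple[int, int]
    min_cds_aa: int = 250
    min_final_aa: int = 280
    max_window_gaps: int = 7
    max_consecutive_x: int = 5

    @property
    def anchor_residue(self) -> str:
        return self.reference_seq[self.anchor_index - 1]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(seq: str) -> str:
    n = len(seq) // 3 * 3
    return str(Seq(seq[:n]).translate())


def extend_orf(
    region: BestHitRegion,
    assembly: GenomeAssembly,
    family: str | None = None,
    min_cds_aa: int = 250,
    call_id: str | None = None,
) -> GeneCall:
    """Extend a best-hit region to the longest CDS and collect disruption evidence.

    Works on the coding strand: walks upstream in frame to the farthest ATG
    not preceded (in frame, downstream of a stop codon) and downstream to
    the first stop codon.  Internal stops within the hit span, frame
    conflicts among the region's member hits, and walks that fall off the
    scaffold are recorded as evidence.  Candidates shorter than
    ``min_cds_aa`` get ``short-cds`` evidence.
    """
    seq = assembly.scaffolds.get(region.scaffold_id)
    if seq is None:
        raise ValueError(f"unknown scaffold {region.scaffold_id!r}")
    if region.start < 0 or region.end > len(seq):
        raise ValueError(
            f"region [{region.start}, {region.end}) outside scaffold "
            f"{region.scaffold_id!r} of length {len(seq)}"
        )
    L = len(seq)
    if region.strand == "+":
        cseq = seq
        c_start, c_end = region.start, region.end
    else:
        cseq = _revcomp(seq)
        c_start, c_end = L - region.end, L - region.start

    evidence: list[str] = []
    pos_frames = {f for f in region.frames if f != 0}
    if len({abs(f) - 1 for f in pos_frames if (f > 0) == (region.strand == "+")}) > 1:
        evidence.append(f"frameshift@{region.start}")

    # downstream walk: first in-frame stop at/after the hit start
    stop_pos = None
    p = c_start
    while p + 3 <= L:
        codon = cseq[p : p + 3]
        if codon in STOPS:
            if p + 3 <= c_end:
                evidence.append(f"internal-stop@{(p - c_start) // 3}")
                # keep scanning: CDS ends at the first stop anyway
            stop_pos = p
            break
        p += 3
    if stop_pos is None:
        evidence.append("contig-end-3prime")
        cds_end = c_start + (L - c_start) // 3 * 3
    else:
        cds_end = stop_pos + 3  # include the stop codon in the CDS interval

    # upstream walk: back in frame until a stop codon or the scaffold start
    bound = None  # coding-strand position of first codon eligible as start
    p = c_start - 3
    hit_5prime_open = False
    while p >= 0:
        if cseq[p : p + 3] in STOPS:
            bound = p + 3
            break
        p -= 3
    if bound is None:
        bound = c_start % 3
        hit_5prime_open = True
        evidence.append("contig-end-5prime")

    # farthest upstream ATG between the bound and the first stop/hit end
    search_end = stop_pos if stop_pos is not None else cds_end
    atg = None
    p = bound
    while p + 3 <= search_end:
        if cseq[p : p + 3] == "ATG":
            atg = p
            break
        p += 3
    if atg is not None and not (hit_5prime_open and atg > c_start):
        cds_start = atg
        if atg <= c_start and "contig-end-5prime" in evidence:
            # an in-frame ATG upstream anchors the start; 5' end is closed
            evidence.remove("contig-end-5prime")
            hit_5prime_open = False
    else:
        cds_start = bound if hit_5prime_open else c_start
        if not hit_5prime_open:
            evidence.append("no-atg")

    coding = cseq[cds_start:cds_end]
    protein = _translate(coding)
    if protein.endswith("*"):
        protein = protein[:-1]
    internal = [i for i, aa in enumerate(protein) if aa == "*"]
    for i in internal:
        tag = f"internal-stop@{i}"
        if tag not in evidence:
            evidence.append(tag)
    run = 0
    for aa in protein:
        run = run + 1 if aa == "X" else 0
        if run >= 5:
            evidence.append("long-x-run")
            break
    if len(protein.replace("*", "")) < min_cds_aa:
        evidence.append("short-cds")

    if region.strand == "+":
        f_start, f_end = cds_start, cds_end
    else:
        f_start, f_end = L - cds_end, L - cds_start
    return GeneCall(
        call_id=call_id or f"{region.scaffold_id}:{f_start}-{f_end}({region.strand})",
        family=family or region.category,
        status="candidate",
        scaffold_id=region.scaffold_id,
        strand=region.strand,
        start=f_start,
        end=f_end,
        protein=protein,
        evidence=evidence,
    )


def classify_call(candidate: GeneCall, min_cds_aa: int = 250) -> GeneCall:
    """Final intact/truncated/pseudogene assignment from collected evidence.

    Total over candidates: intact if every gate passed, truncated if the
    reading runs to a scaffold terminus with no internal disruption, else
    pseudogene.
    """
    if candidate.has_disruption:
        status = "pseudogene"
    elif candidate.contig_end_sides:
        status = "truncated"
    elif (
        candidate.protein.startswith("M")
        and len(candidate.protein) >= min_cds_aa
        and "no-atg" not in candidate.evidence
        and "short-cds" not in candidate.evidence
    ):
        status = "intact"
    else:
        status = "pseudogene"
    return replace(candidate, status=status)


# ----------------------- profile-anchored refinement -----------------------


def build_profile_msa(
    candidates: Mapping[str, str], profile: FamilyProfile
) -> dict[str, str]:
    """Pseudo-MSA of candidates against the family reference (center-star merge).

    Each candidate is globally aligned to the reference; insertions relative
    to the reference are merged across candidates so all rows share one
    coordinate system.  Adequate for anchor location and window gap counts;
    it is not a general progressive aligner.
    """
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    ref = profile.reference_seq
    R = len(ref)
    # per candidate: list of R+1 insertion strings (before each ref residue, plus tail)
    parsed: dict[str, list[list[str]]] = {}
    ins_max = [0] * (R + 1)
    for cid, cseq in candidates.items():
        if not cseq:
            raise ValueError(f"empty candidate protein {cid!r}")
        aln = aligner.align(ref, cseq)[0]
        a_ref, a_cand = str(aln[0]), str(aln[1])
        slots: list[list[str]] = [[] for _ in range(R + 1)]
        aligned_to: list[str] = []  # candidate char (or '-') aligned to each ref residue
        r = 0
        for ra, ca in zip(a_ref, a_cand):
            if ra == "-":
                slots[r].append(ca)
            else:
                aligned_to.append(ca)
                r += 1
        parsed[cid] = [slots, aligned_to]  # type: ignore[list-item]
        for i, s in enumerate(slots):
            ins_max[i] = max(ins_max[i], len(s))

    msa: dict[str, str] = {}
    ref_row = []
    for i in range(R):
        ref_row.append("-" * ins_max[i] + ref[i])
    ref_row.append("-" * ins_max[R])
    msa[profile.reference_id] = "".join(ref_row)
    for cid, (slots, aligned_to) in parsed.items():
        row = []
        for i in range(R):
            ins = "".join(slots[i])
            row.append(ins.rjust(ins_max[i], "-") + aligned_to[i])
        row.append("".join(slots[R]).ljust(ins_max[R], "-"))
        msa[cid] = "".join(row)
    return msa


def _ref_columns(msa: Mapping[str, str], reference_id: str) -> list[int]:
    """Alignment column index of each reference residue (0-based)."""
    try:
        ref_row = msa[reference_id]
    except KeyError:
        raise ValueError(f"reference {reference_id!r} absent from alignment") from None
    return [c for c, ch in enumerate(ref_row) if ch != "-"]


def select_initiation_codon(
    msa: Mapping[str, str],
    profile: FamilyProfile,
) -> dict[str, tuple[str, int]]:
    """Choose each candidate's initiation codon within the anchored window.

    Position 0 is the alignment column of the reference anchor residue.
    A candidate with zero residues before position 0 is discarded; otherwise
    the most upstream M among positions ``-atg_window..0`` becomes the new
    start.  Candidates with no M in the window are discarded.

    Returns ``{candidate_id: (trimmed_protein, n_residues_trimmed)}`` for
    survivors only.
    """
    cols = _ref_columns(msa, profile.reference_id)
    if profile.anchor_index - 1 >= len(cols):
        raise ValueError(
            f"reference alignment lacks anchor residue {profile.anchor_index}"
        )
    anchor_col = cols[profile.anchor_index - 1]
    out: dict[str, tuple[str, int]] = {}
    for cid, row in msa.items():
        if cid == profile.reference_id:
            continue
        if len(row) != len(msa[profile.reference_id]):
            raise ValueError(f"alignment rows differ in length ({cid!r})")
        k = sum(1 for ch in row[:anchor_col] if ch != "-")  # N-terminal length
        if k == 0:
            continue  # zero-length N-terminal portion: discard
        seq = row.replace("-", "")
        best_pos = None
        best_idx = None
        for i in range(len(seq)):
            pos = i - k
            if pos > 0:
                break
            if seq[i] == "M" and -profile.atg_window <= pos <= 0:
                if best_pos is None or pos < best_pos:
                    best_pos, best_idx = pos, i
        if best_idx is None:
            continue  # no initiation codon in the window: discard
        out[cid] = (seq[best_idx:], best_idx)
    return out


def conserved_window_gap_filter(
    msa: Mapping[str, str],
    profile: FamilyProfile,
) -> list[str]:
    """Retain candidates without excessive gaps in the conserved window.

    Candidates with ``max_window_gaps`` or more gap characters across the
    window columns, or shorter than ``min_final_aa`` residues, are removed.
    Returns the ids of retained candidates.
    """
    cols = _ref_columns(msa, profile.reference_id)
    lo, hi = profile.conserved_window_span
    if hi - 1 >= len(cols):
        raise ValueError("conserved window columns absent from alignment")
    window_cols = cols[lo - 1 : hi]
    retained = []
    for cid, row in msa.items():
        if cid == profile.reference_id:
            continue
        gaps = sum(1 for c in window_cols if row[c] == "-")
        if gaps >= profile.max_window_gaps:
            continue
        if len(row.replace("-", "")) < profile.min_final_aa:
            continue
        retained.append(cid)
    return retained


# ------------------------- refinement filters i-iv -------------------------


def _embedded(short_seq: str, long_seq: str, min_identity: float, min_coverage: float) -> bool:
    """Containment test: the short contig aligns within the long one."""
    try:
        import edlib
    except ImportError:  # pragma: no cover - edlib is an install-time dep
        edlib = None
    if edlib is not None:
        res = edlib.align(short_seq, long_seq, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist < 0:
            return False
        return 1.0 - dist / len(short_seq) >= min_identity * min_coverage
    return short_seq in long_seq


def apply_dedup_filters(
    calls: Sequence[GeneCall],
    assembly: GenomeAssembly,
    min_contig_bp: int = 1000,
    embed_nt_identity: float = 0.99,
    embed_coverage: float = 0.95,
    aa_identity: float = 0.99,
) -> tuple[list[GeneCall], list[str]]:
    """The four refinement filters, applied in order.

    (i)   drop calls on contigs shorter than ``min_contig_bp``;
    (ii)  when one contig is embedded in a longer one at high nucleotide
          identity and the genes are near-identical in protein, drop the
          call on the shorter contig;
    (iii) drop exact protein duplicates among intact/truncated calls
          (truncated contained in intact → drop truncated; shorter of two
          nested truncated → drop);
    (iv)  merge an N-terminus-missing and a C-terminus-missing truncated
          pair with a 100%-identical, ungapped overlap into one intact call.

    Returns the surviving calls and a log of removals/merges tagged by rule.
    """
    log: list[str] = []
    lengths = assembly.lengths

    # (i) short contigs
    kept: list[GeneCall] = []
    for c in calls:
        if lengths.get(c.scaffold_id, 0) < min_contig_bp:
            log.append(f"i\tremoved\t{c.call_id}\tcontig<{min_contig_bp}bp")
        else:
            kept.append(c)

    # (ii) embedded contigs
    by_scaf: dict[str, list[GeneCall]] = {}
    for c in kept:
        by_scaf.setdefault(c.scaffold_id, []).append(c)
    drop: set[str] = set()
    scafs = sorted(by_scaf, key=lambda s: (lengths[s], s))
    for i, s_short in enumerate(scafs):
        for s_long in scafs[i + 1 :]:
            if lengths[s_long] <= lengths[s_short]:
                continue
            if not _embedded(
                assembly.scaffolds[s_short],
                assembly.scaffolds[s_long],
                embed_nt_identity,
                embed_coverage,
            ):
                continue
            for c_short in by_scaf[s_short]:
                for c_long in by_scaf[s_long]:
                    if c_short.call_id in drop or c_long.call_id in drop:
                        continue
                    if pairwise_identity(c_short.protein, c_long.protein) > aa_identity:
                        drop.add(c_short.call_id)
                        log.append(f"ii\tremoved\t{c_short.call_id}\tembedded-in\t{s_long}")
    kept = [c for c in kept if c.call_id not in drop]

    # (iii) exact amino-acid duplicates among intact/truncated
    it_calls = sorted(
        (c for c in kept if c.status in ("intact", "truncated")),
        key=lambda c: (-len(c.protein), c.call_id),
    )
    drop = set()
    for i, a in enumerate(it_calls):
        if a.call_id in drop:
            continue
        for b in it_calls[i + 1 :]:
            if b.call_id in drop:
                continue
            if a.status == "intact" and b.status == "intact":
                if a.protein == b.protein:
                    drop.add(b.call_id)
                    log.append(f"iii\tremoved\t{b.call_id}\tduplicate-of\t{a.call_id}")
            elif b.status == "truncated" and b.protein and b.protein in a.protein:
                # truncated contained in a longer intact/truncated gene
                if a.status == "intact" or len(a.protein) > len(b.protein):
                    drop.add(b.call_id)
                    log.append(f"iii\tremoved\t{b.call_id}\tcontained-in\t{a.call_id}")
    kept = [c for c in kept if c.call_id not in drop]

    # (iv) combine complementary truncated pairs
    missing_c = [
        c for c in kept if c.status == "truncated" and "3prime" in c.contig_end_sides
    ]
    missing_n = [
        c for c in kept if c.status == "truncated" and "5prime" in c.contig_end_sides
    ]
    merged_away: set[str] = set()
    merged_calls: list[GeneCall] = []
    for a in sorted(missing_c, key=lambda c: c.call_id):
        if a.call_id in merged_away:
            continue
        for b in sorted(missing_n, key=lambda c: c.call_id):
            if b.call_id in merged_away or b.call_id == a.call_id:
                continue
            k = _max_overlap(a.protein, b.protein)
            if k >= 1:
                merged = GeneCall(
                    call_id=f"{a.call_id}+{b.call_id}",
                    family=a.family,
                    status="intact",
                    scaffold_id=f"{a.scaffold_id}+{b.scaffold_id}",
                    strand=a.strand,
                    start=a.start,
                    end=b.end,
                    protein=a.protein + b.protein[k:],
                    evidence=[f"merged:{a.call_id}+{b.call_id}"],
                )
                merged_away.update({a.call_id, b.call_id})
                merged_calls.append(merged)
                log.append(f"iv\tmerged\t{a.call_id}\t{b.call_id}\t->\t{merged.call_id}")
                break
    kept = [c for c in kept if c.call_id not in merged_away] + merged_calls
    return kept, log


def _max_overlap(a: str, b: str) -> int:
    """Longest k with a[-k:] == b[:k] (ungapped, 100% identical overlap)."""
    for k in range(min(len(a), len(b)), 0, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


# ------------------------------- clustering --------------------------------

_identity_aligner = PairwiseAligner()
_identity_aligner.mode = "global"
_identity_aligner.match_score = 2
_identity_aligner.mismatch_score = -1
_identity_aligner.open_gap_score = -5
_identity_aligner.extend_gap_score = -0.5


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / columns, terminal gaps excluded."""
    if not a or not b:
        raise ValueError("empty sequence in identity computation")
    if a == b:
        return 1.0
    aln = _identity_aligner.align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    lo = 0
    hi = len(ra)
    while lo < hi and (ra[lo] == "-" or rb[lo] == "-"):
        lo += 1
    while hi > lo and (ra[hi - 1] == "-" or rb[hi - 1] == "-"):
        hi -= 1
    cols = hi - lo
    if cols == 0:
        return 0.0
    matches = sum(1 for x, y in zip(ra[lo:hi], rb[lo:hi]) if x == y and x != "-")
    return matches / cols


def identity_cluster(
    proteins: Mapping[str, str], threshold: float
) -> list[dict]:
    """Single-linkage groups at a pairwise-identity threshold.

    Returns one record per group: ``{"members": [...], "representative": id}``
    with the representative the longest member (ties by lexicographic id).
    """
    if not proteins:
        raise ValueError("identity_cluster requires at least one protein")
    ids = sorted(proteins)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if pairwise_identity(proteins[a], proteins[b]) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        rep = min(members, key=lambda m: (-len(proteins[m]), m))
        out.append({"members": sorted(members), "representative": rep})
    return out


V1R_PROFILE_NOTE = """Synthetic reference profile: the reference sequence is a
constructed consensus-like V1R protein carrying the conserved 7TM window, not
a database dump."""

def _make_synthetic_reference(window: str, window_start_1based: int, length: int, seed: int) -> str:
    import random

    rng = random.Random(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    res = [rng.choice(aas) for _ in range(length)]
    res[0] = "M"
    for i, ch in enumerate(window):
        res[window_start_1based - 1 + i] = ch
    return "".join(res)


# Default profiles. Reference sequences are synthetic consensus-like receptor
# proteins (see V1R_PROFILE_NOTE); anchor/window geometry follows the mouse
# Vmn1r1 / human TAS2R5 conventions used in the field.
_V1R_REF = _make_synthetic_reference("MFVSSGYATFSPLVF", 274, 300, seed=11)
_V1R_REF = _V1R_REF[:23] + "G" + _V1R_REF[24:]  # anchor: residue 24 is G
V1R_PROFILE = FamilyProfile(
    family="V1R",
    reference_id="V1R-ref",
    reference_seq=_V1R_REF,
    anchor_index=24,
    atg_window=40,
    conserved_window_span=(274, 288),
)

_T2R_REF = _make_synthetic_reference("MFVSSGYATFSPLVF", 270, 300, seed=13)
_T2R_REF = _T2R_REF[:15] + "E" + _T2R_REF[16:]  # anchor: residue 16 is E
T2R_PROFILE = FamilyProfile(
    family="T2R",
    reference_id="T2R-ref",
    reference_seq=_T2R_REF,
    anchor_index=16,
    atg_window=27,
    conserved_window_span=(270, 284),
)
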