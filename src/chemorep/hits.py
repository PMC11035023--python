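"""Translated homology hits and per-locus best-hit reduction.

Receptor gene mining starts from translated searches of family query
proteins against a genome.  Because queries within a family resemble each
other, many queries hit the same locus; each locus is reduced to a single
"best-hit" region labelled with the query giving the lowest e-value there.

Hits are ingested from the 12-column tabular search format (query, subject,
%identity, alignment length, mismatches, gap opens, qstart, qend, sstart,
send, evalue, bitscore) or produced by a built-in naive translated search
used for fixtures and round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "HitRecord",
    "BestHitRegion",
    "parse_tabular_hits",
    "merge_and_best_hit",
    "naive_translated_search",
]


@dataclass(frozen=True)
class HitRecord:
    """One translated-search hit in forward-strand genome coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand of the
    scaffold; ``frame`` follows the usual convention (+1..+3 forward,
    -1..-3 on the reverse complement), 0 when unknown.
    """

    query_id: str
    scaffold_id: str
    strand: str
    start: int
    end: int
    evalue: float
    bitscore: float
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass
class BestHitRegion:
    """A merged same-scaffold, same-strand locus with its winning query."""

    scaffold_id: str
    strand: str
    start: int
    end: int
    query_id: str
    evalue: float
    bitscore: float
    n_hits: int
    category: str
    frames: tuple[int, ...] = ()
    frame: int = 0  # winning hit's frame


def parse_tabular_hits(path: str | Path, evalue_cutoff: float = 1e-20) -> list[HitRecord]:
    """Read 12-column tabular hits, dropping rows above the e-value cutoff.

    Subject coordinates are 1-based inclusive with reverse-strand hits
    encoded as sstart > send; they are normalised here to 0-based half-open
    forward-strand intervals with an explicit strand.  Comment lines
    (leading ``#``) are skipped.  An empty file yields an empty list.
    """
    out: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                query_id, subject_id = fields[0], fields[1]
                sstart, send = int(fields[8]), int(fields[9])
                evalue, bitscore = float(fields[10]), float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row ({exc})") from None
            if evalue > evalue_cutoff:
                continue
            if sstart <= send:
                strand, start, end = "+", sstart - 1, send
            else:
                strand, start, end = "-", send - 1, sstart
            out.append(
                HitRecord(
                    query_id=query_id,
                    scaffold_id=subject_id,
                    strand=strand,
                    start=start,
                    end=end,
                    evalue=evalue,
                    bitscore=bitscore,
                )
            )
    return out


def _hit_sort_key(h: HitRecord):
    return (h.evalue, -h.bitscore, h.query_id, h.scaffold_id, h.start)


def merge_and_best_hit(
    hits: Sequence[HitRecord],
    query_category_map: Mapping[str, str],
    merge_gap: int = 0,
) -> list[BestHitRegion]:
    """Group overlapping same-scaffold, same-strand hits and keep the best query.

    Hits whose intervals overlap (transitively; intervals closer than
    ``merge_gap`` bp also merge) form one region.  The winner is the member
    with the lowest e-value, ties broken by higher bitscore then
    lexicographic query id; the region takes the winner's category from
    ``query_category_map``.
    """
    missing = sorted({h.query_id for h in hits} - set(query_category_map))
    if missing:
        raise KeyError(f"queries missing from category map: {missing}")
    by_key: dict[tuple[str, str], list[HitRecord]] = {}
    for h in hits:
        by_key.setdefault((h.scaffold_id, h.strand), []).append(h)

    regions: list[BestHitRegion] = []
    for (scaffold_id, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda h: (h.start, h.end, _hit_sort_key(h)))
        cluster: list[HitRecord] = []
        cluster_end = -1
        clusters: list[list[HitRecord]] = []
        for h in group:
            if cluster and h.start > cluster_end + merge_gap:
                clusters.append(cluster)
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
        if cluster:
            clusters.append(cluster)
        for members in clusters:
            winner = min(members, key=_hit_sort_key)
            regions.append(
                BestHitRegion(
                    scaffold_id=scaffold_id,
                    strand=strand,
                    start=min(m.start for m in members),
                    end=max(m.end for m in members),
                    query_id=winner.query_id,
                    evalue=winner.evalue,
                    bitscore=winner.bitscore,
                    n_hits=len(members),
                    category=query_category_map[winner.query_id],
                    frames=tuple(sorted({m.frame for m in members})),
                    frame=winner.frame,
                )
            )
    return regions


# --- naive translated search (fixture/test stand-in for an external tool) ---


def _six_frame_translations(seq: str) -> list[tuple[int, str, int, str]]:
    """Yield (frame, strand, nt_offset, protein) for all six reading frames.

    ``nt_offset`` is the 0-based offset of the frame's first codon on the
    *coding* strand (the reverse complement for negative frames).
    """
    frames = []
    rc = str(Seq(seq).reverse_complement())
    for off in range(3):
        n = (len(seq) - off) // 3 * 3
        if n >= 3:
            frames.append((off + 1, "+", off, str(Seq(seq[off : off + n]).translate())))
            frames.append((-(off + 1), "-", off, str(Seq(rc[off : off + n]).translate())))
    return frames


def _coding_to_forward(aa_start: int, aa_end: int, off: int, strand: str, seq_len: int):
    """Map a protein segment [aa_start, aa_end) in a frame to forward-strand nt coords."""
    nt_start = off + 3 * aa_start
    nt_end = off + 3 * aa_end
    if strand == "+":
        return nt_start, nt_end
    return seq_len - nt_end, seq_len - nt_start


def naive_translated_search(
    queries: Mapping[str, str],
    assembly,
    word_len: int = 8,
    min_aln_aa: int = 30,
    min_identity: float = 0.4,
) -> list[HitRecord]:
    """Seed-and-extend protein-vs-six-frame-translation search.

    Exact ``word_len``-residue matches seed ungapped extensions that continue
    while segment identity stays at or above ``min_identity``; hits shorter
    than ``min_aln_aa`` residues are dropped.  The score is the identity
    count and the pseudo-e-value is ``2**-score`` — a monotone rank proxy,
    not a search-tool statistic.  Intended for fixtures and round-trip tests.
    """
    if not queries:
        raise ValueError("empty query set")
    if word_len < 3:
        raise ValueError("word_len must be >= 3 amino acids")

    hits: list[HitRecord] = []
    for scaffold_id, seq in assembly.scaffolds.items():
        for frame, strand, off, prot in _six_frame_translations(seq):
            # index genome words per frame
            words: dict[str, list[int]] = {}
            for i in range(len(prot) - word_len + 1):
                w = prot[i : i + word_len]
                if "*" not in w and "X" not in w:
                    words.setdefault(w, []).append(i)
            for query_id, qseq in queries.items():
                seen_spans: set[tuple[int, int]] = set()
                for qi in range(len(qseq) - word_len + 1):
                    w = qseq[qi : qi + word_len]
                    for si in words.get(w, ()):
                        span = _extend(qseq, prot, qi, si, word_len, min_identity)
                        if span is None:
                            continue
                        qs, ss, length, matches = span
                        if length < min_aln_aa:
                            continue
                        key = (ss, ss + length)
                        if key in seen_spans:
                            continue
                        seen_spans.add(key)
                        start, end = _coding_to_forward(
                            ss, ss + length, off, strand, len(seq)
                        )
                        hits.append(
                            HitRecord(
                                query_id=query_id,
                                scaffold_id=scaffold_id,
                                strand=strand,
                                start=start,
                                end=end,
                                evalue=2.0 ** (-matches),
                                bitscore=float(matches),
                                frame=frame,
                            )
                        )
    # deduplicate identical spans per query, keep best
    best: dict[tuple, HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.scaffold_id, h.strand, h.start, h.end)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.scaffold_id, h.strand, h.start, h.query_id))


def _extend(qseq: str, prot: str, qi: int, si: int, word_len: int, min_identity: float):
    """Ungapped extension of a seed in both directions; greedy, stop at '*' or low identity."""
    # left extension
    left = 0
    matches_left = 0
    best_left = (0, 0)
    while qi - left - 1 >= 0 and si - left - 1 >= 0:
        q = qseq[qi - left - 1]
        s = prot[si - left - 1]
        if s == "*":
            break
        left += 1
        if q == s:
            matches_left += 1
        ext_total = left
        if matches_left >= min_identity * ext_total:
            best_left = (left, matches_left)
    # right extension beyond the word
    right = 0
    matches_right = 0
    best_right = (0, 0)
    while qi + word_len + right < len(qseq) and si + word_len + right < len(prot):
        q = qseq[qi + word_len + right]
        s = prot[si + word_len + right]
        if s == "*":
            break
        right += 1
        if q == s:
            matches_right += 1
        if matches_right >= min_identity * right:
            best_right = (right, matches_right)
    left, matches_left = best_left
    right, matches_right = best_right
    length = word_len + left + right
    matches = word_len + matches_left + matches_right
    if matches < min_identity * length:
        return None
    return qi - left, si - left, length, matches
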