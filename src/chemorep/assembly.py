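"""Genome assembly handling and the scaffold-truncation probability model.

A draft genome assembly is a bag of scaffolds.  A multi-exon receptor gene
spanning ``L`` bp cannot be fully recovered from a scaffold shorter than
``L``, and even on a longer scaffold it is cut whenever its midpoint falls
within ``L/2`` of either scaffold end.  Averaging over a uniform placement of
the gene midpoint across the whole assembly gives the closed-form truncation
probability

    P = (n1 * L + sum of short-scaffold lengths) / N

where ``n1`` counts scaffolds longer than ``L`` and ``N`` is the total
assembly length.  ``truncation_probability`` evaluates the closed form and
``truncation_probability_mc`` checks it by direct Monte-Carlo placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeAssembly",
    "AssemblyStats",
    "TruncationEstimate",
    "assembly_stats",
    "truncation_probability",
    "truncation_probability_mc",
]

_IUPAC_NT = set("ACGTRYSWKMBDHVN")


@dataclass
class GenomeAssembly:
    """Named scaffolds with nucleotide sequences (uppercase IUPAC codes)."""

    scaffolds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.scaffolds.items():
            seq = str(seq).upper()
            if len(seq) < 1:
                raise ValueError(f"scaffold {name!r} is empty")
            bad = set(seq) - _IUPAC_NT
            if bad:
                raise ValueError(
                    f"scaffold {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            clean[name] = seq
        self.scaffolds = clean

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeAssembly":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records found in {path}")
        return cls(records)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self.scaffolds.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def __len__(self) -> int:
        return len(self.scaffolds)


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_bp: int
    n50: int
    gc_fraction: float
    min_len_cutoff: int


@dataclass(frozen=True)
class TruncationEstimate:
    """Components of the truncation-probability formula.

    ``L``  mean gene span (initiation to stop codon, introns included), bp
    ``n1`` scaffolds longer than L; ``n2`` scaffolds of length <= L
    ``sum_short`` summed length of the n2 short scaffolds
    ``N``  entire assembly length; ``P`` the estimated truncation probability
    """

    L: float
    n1: int
    n2: int
    sum_short: int
    N: int
    P: float


def _n50(lengths: Iterable[int]) -> int:
    """Shortest scaffold in the smallest set of longest scaffolds covering half the total."""
    sizes = sorted(lengths, reverse=True)
    half = sum(sizes) / 2.0
    acc = 0
    for s in sizes:
        acc += s
        if acc >= half:
            return s
    raise AssertionError("unreachable: empty length list")


def assembly_stats(assembly: GenomeAssembly, min_len_cutoff: int = 1) -> AssemblyStats:
    """Scaffold count, total length, N50, and GC fraction above a length cutoff.

    Scaffolds shorter than ``min_len_cutoff`` are excluded from every
    statistic.  GC is computed over unambiguous bases only.
    """
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    kept = {n: s for n, s in assembly.scaffolds.items() if len(s) >= min_len_cutoff}
    if not kept:
        raise ValueError(
            f"no scaffolds of length >= {min_len_cutoff} bp remain in the assembly"
        )
    lengths = [len(s) for s in kept.values()]
    gc = at = 0
    for seq in kept.values():
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous bases; GC fraction undefined")
    return AssemblyStats(
        n_scaffolds=len(kept),
        total_bp=sum(lengths),
        n50=_n50(lengths),
        gc_fraction=gc / (gc + at),
        min_len_cutoff=min_len_cutoff,
    )


def truncation_probability(
    assembly: GenomeAssembly | Mapping[str, int] | Iterable[int],
    L: float,
) -> TruncationEstimate:
    """Closed-form probability that a gene of span ``L`` is cut by scaffold ends.

    Accepts a :class:`GenomeAssembly`, a mapping of scaffold id -> length, or a
    bare iterable of scaffold lengths.  Scaffolds of length <= L count as
    "short" (a gene there is truncated wherever it sits); on longer scaffolds
    the truncated zone is L/2 at each end.  No length cutoff is applied: N is
    the entire assembly length.
    """
    if L <= 0:
        raise ValueError(f"gene span L must be positive, got {L}")
    if isinstance(assembly, GenomeAssembly):
        lengths = list(assembly.lengths.values())
    elif isinstance(assembly, Mapping):
        lengths = list(assembly.values())
    else:
        lengths = list(assembly)
    if not lengths:
        raise ValueError("empty assembly")
    lengths_arr = np.asarray(lengths, dtype=float)
    long_mask = lengths_arr > L
    n1 = int(long_mask.sum())
    n2 = len(lengths) - n1
    sum_short = int(lengths_arr[~long_mask].sum())
    N = int(lengths_arr.sum())
    numerator = n1 * L + sum_short
    if numerator > N + 1e-9:
        raise AssertionError(
            "truncation numerator exceeds assembly length; inconsistent inputs"
        )
    P = min(numerator / N, 1.0)
    return TruncationEstimate(L=L, n1=n1, n2=n2, sum_short=sum_short, N=N, P=P)


def truncation_probability_mc(
    assembly: GenomeAssembly | Mapping[str, int] | Iterable[int],
    L: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo oracle for :func:`truncation_probability`.

    Places the gene midpoint uniformly over the concatenated assembly and
    counts placements where the ``[mid - L/2, mid + L/2]`` span is not fully
    contained in a single scaffold.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if L <= 0:
        raise ValueError(f"gene span L must be positive, got {L}")
    if isinstance(assembly, GenomeAssembly):
        lengths = list(assembly.lengths.values())
    elif isinstance(assembly, Mapping):
        lengths = list(assembly.values())
    else:
        lengths = list(assembly)
    if not lengths:
        raise ValueError("empty assembly")
    lengths_arr = np.asarray(lengths, dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(lengths_arr)])
    rng = np.random.default_rng(seed)
    mids = rng.uniform(0.0, edges[-1], size=n_draws)
    idx = np.searchsorted(edges, mids, side="right") - 1
    idx = np.clip(idx, 0, len(lengths_arr) - 1)
    offset = mids - edges[idx]
    dist_to_end = np.minimum(offset, lengths_arr[idx] - offset)
    truncated = dist_to_end < L / 2.0
    return float(truncated.mean())
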