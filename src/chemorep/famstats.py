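"""Repertoire summaries and cross-family synchrony statistics.

Covers the comparative layer of the pipeline: per-family repertoire tables
(totals, per-species means, coefficients of variation, per-OGG dispersion),
variance-ratio tests between families' per-OGG counts, Spearman rank
correlations of per-branch gain/loss counts between families, and
phylogenetically independent contrasts (PIC) for cross-species trait
correlations with shared ancestry removed.

Conventions: sample (n-1) variances throughout; Spearman uses average
ranks, with exact permutation p-values below 10 observations and the t
approximation otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "repertoire_summary",
    "ogg_dispersion_test",
    "spearman",
    "correlate_branch_events",
    "ContrastSet",
    "pic_contrasts",
    "pic_correlation",
]


def repertoire_summary(
    table: pd.DataFrame,
    ogg_sizes: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Family-level repertoire statistics from a species x family count table.

    ``table`` holds intact gene counts (rows = species, columns = families);
    ``ogg_sizes`` optionally maps family -> per-OGG member counts.  Returns
    one row per statistic: total, mean and CV of genes per species, and
    (when OGG sizes are given) OGG count plus mean/max/SD of genes per OGG.
    No rounding is applied; presentation rounding is the caller's concern.
    """
    if table.shape[0] == 0:
        raise ValueError("repertoire table has no species")
    rows = {
        "total_intact": table.sum(axis=0).astype(float),
        "mean_per_species": table.mean(axis=0),
        "cv_per_species": table.std(axis=0, ddof=1) / table.mean(axis=0),
    }
    if ogg_sizes is not None:
        n_oggs, mean_ogg, max_ogg, sd_ogg = {}, {}, {}, {}
        for fam in table.columns:
            sizes = np.asarray(ogg_sizes.get(fam, []), dtype=float)
            n_oggs[fam] = float(len(sizes))
            mean_ogg[fam] = sizes.mean() if sizes.size else np.nan
            max_ogg[fam] = sizes.max() if sizes.size else np.nan
            sd_ogg[fam] = sizes.std(ddof=1) if sizes.size > 1 else np.nan
        rows["n_oggs"] = pd.Series(n_oggs)
        rows["mean_per_ogg"] = pd.Series(mean_ogg)
        rows["max_per_ogg"] = pd.Series(max_ogg)
        rows["sd_per_ogg"] = pd.Series(sd_ogg)
    return pd.DataFrame(rows).T[table.columns]


def ogg_dispersion_test(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided variance-ratio F test between two per-OGG count samples.

    F is the ratio of sample variances (a over b); the two-sided p-value is
    2 * min(P[F <= f], P[F >= f]) under F(n_a - 1, n_b - 1).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator sample")
    f = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    r_S is the Pearson correlation of the average-rank vectors.  The
    p-value is exact (full permutation of one margin) for n < 10 and the
    usual t approximation with n - 2 df otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need >= 3 paired observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = _pearson(rx, ry)
    if n < 10:
        obs = abs(r)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = _pearson(rx[list(perm)], ry)
            total += 1
            if abs(rp) >= obs - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), n - 2)
    return float(r), float(p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def correlate_branch_events(
    tables: Mapping[str, Mapping[str, float]],
    mode: str = "gains",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations of per-branch event counts.

    ``tables`` maps family -> {branch id -> gains or losses}; every family
    must cover the same branch set.  Per-branch gain/loss counts are
    treated as independent observations (each branch's events were
    estimated separately per OGG).  Returns (r matrix, p matrix).
    """
    fams = list(tables)
    branch_sets = {frozenset(tables[f]) for f in fams}
    if len(branch_sets) != 1:
        raise ValueError("families cover different branch sets")
    branches = sorted(branch_sets.pop())
    if len(branches) < 3:
        raise ValueError("need >= 3 branches")
    r = pd.DataFrame(np.eye(len(fams)), index=fams, columns=fams)
    p = pd.DataFrame(np.zeros((len(fams), len(fams))), index=fams, columns=fams)
    for i, a in enumerate(fams):
        for b in fams[i + 1 :]:
            va = [tables[a][br] for br in branches]
            vb = [tables[b][br] for br in branches]
            rs, pv = spearman(va, vb)
            r.loc[a, b] = r.loc[b, a] = rs
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


# ----------------- phylogenetically independent contrasts ------------------


@dataclass
class ContrastSet:
    """Standardized contrasts (one per internal node, n_leaves - 1 total)."""

    contrasts: np.ndarray
    node_order: list[str]


def pic_contrasts(
    tree: dendropy.Tree,
    trait: Mapping[str, float],
    resolve_polytomies: bool = False,
) -> ContrastSet:
    """Felsenstein's independent contrasts by the pruning recursion.

    Requires a rooted, fully bifurcating tree with branch lengths and a
    trait value per leaf.  Each internal node contributes the contrast
    ``(x_i - x_j) / sqrt(v_i + v_j)``; the node's ancestral value is the
    variance-weighted average of its children and its parent branch is
    lengthened by ``v_i * v_j / (v_i + v_j)``.
    """
    work = tree.clone(depth=1)
    if resolve_polytomies:
        work.resolve_polytomies(limit=2, update_bipartitions=False)
    contrasts: list[float] = []
    order: list[str] = []

    def prune(node):
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise ValueError(f"no trait value for leaf {label!r}")
            return float(trait[label]), float(node.edge.length or 0.0)
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ValueError(
                "tree must be fully bifurcating for independent contrasts"
            )
        (xi, vi), (xj, vj) = (prune(k) for k in kids)
        if vi + vj <= 0:
            raise ValueError("zero combined branch length at a contrast node")
        contrasts.append((xi - xj) / math.sqrt(vi + vj))
        order.append(
            node.label
            or ",".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
        )
        x = (xi / vi + xj / vj) / (1 / vi + 1 / vj) if vi > 0 and vj > 0 else (
            xi if vj > 0 else xj
        )
        v = (node.edge.length or 0.0) + vi * vj / (vi + vj)
        return x, v

    prune(work.seed_node)
    return ContrastSet(contrasts=np.asarray(contrasts), node_order=order)


def pic_correlation(a: ContrastSet, b: ContrastSet) -> float:
    """Correlation of two traits' contrasts, computed through the origin."""
    x, y = a.contrasts, b.contrasts
    if x.size != y.size:
        raise ValueError("contrast sets differ in size")
    denom = math.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise ValueError("degenerate contrasts (all zero)")
    return float((x * y).sum() / denom)
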