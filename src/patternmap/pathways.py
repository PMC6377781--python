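"""Pathway-database trimming and overlap-based deduplication.

Pathway collections aggregated from several resources (KEGG, Reactome, Wiki
pathways, ...) contain near-duplicate entries and very large catch-all sets
that bias enrichment.  This module trims by size and then merges highly
similar gene sets: the similarity of pathways i and j is the overlap rate

    overlap(i, j) = min(|i|, |j|) / |i ∪ j|

(1 only for identical sets; note two *disjoint* equal-size sets score 0.5 —
this statistic rewards nesting, unlike the Jaccard index).  Pathways are
clustered by average linkage on the distance 1 - overlap and every cluster
below the cut height becomes one merged pathway carrying the union gene set.

The agglomeration is implemented here with an explicit deterministic
tie-break (merge the pair whose smallest member identifiers compare lowest)
so that merged databases are reproducible even when many pairs share the
same linkage distance, which is common for gene-set overlap distances.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import Pathway

__all__ = [
    "OverlapMatrix",
    "MergedPathway",
    "TrimReport",
    "trim_pathways",
    "overlap_rate",
    "overlap_matrix",
    "cluster_and_merge",
]


def overlap_rate(a: frozenset | set, b: frozenset | set) -> float:
    """Overlap rate of two gene sets: min(|a|, |b|) / |a ∪ b|."""
    if not a or not b:
        raise ValueError("overlap_rate requires non-empty gene sets")
    return min(len(a), len(b)) / len(a | b)


@dataclass
class OverlapMatrix:
    """Symmetric pairwise overlap rates for an ordered list of pathways."""

    pathway_ids: list[str]
    rates: np.ndarray  # (n, n), unit diagonal

    def distance(self) -> np.ndarray:
        return 1.0 - self.rates


def overlap_matrix(db: Sequence[Pathway]) -> OverlapMatrix:
    n = len(db)
    rates = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rates[i, j] = rates[j, i] = overlap_rate(db[i].genes, db[j].genes)
    return OverlapMatrix(pathway_ids=[p.pathway_id for p in db], rates=rates)


@dataclass
class TrimReport:
    kept: list[Pathway]
    removed_large: list[Pathway]
    removed_small: list[Pathway]


def trim_pathways(
    db: Sequence[Pathway], max_size: int = 1000, min_size: int = 3
) -> TrimReport:
    """Drop catch-all pathways above ``max_size`` genes and stubs below ``min_size``."""
    if not max_size > min_size >= 1:
        raise ValueError("need max_size > min_size >= 1")
    report = TrimReport([], [], [])
    for pw in db:
        if len(pw.genes) > max_size:
            report.removed_large.append(pw)
        elif len(pw.genes) < min_size:
            report.removed_small.append(pw)
        else:
            report.kept.append(pw)
    return report


@dataclass
class MergedPathway:
    """A cluster of overlapping source pathways, merged into one gene set."""

    merged_id: str
    member_ids: list[str]
    genes: frozenset[str]
    name: str
    height: float  # largest linkage height inside the cluster; 0 for singletons

    def __len__(self) -> int:
        return len(self.genes)


def _merged_id(member_ids: Sequence[str]) -> str:
    digest = hashlib.sha1("\x1f".join(sorted(member_ids)).encode()).hexdigest()[:10]
    return f"MRG_{digest}"


def _average_linkage_clusters(
    dist: np.ndarray, ids: Sequence[str], cut: float
) -> tuple[list[list[int]], dict[frozenset[int], float]]:
    """Agglomerate with average linkage until the minimum distance exceeds the cut.

    Average linkage is monotone (no inversions), so stopping at the cut yields
    exactly the flat clusters of the full dendrogram at that height.  Ties are
    broken by the lexicographically smallest pair of cluster labels, a cluster
    being labelled by the smallest member id.
    """
    n = len(ids)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    label: dict[int, str] = {i: ids[i] for i in range(n)}
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = set(range(n))
    heights: dict[frozenset[int], float] = {}
    while len(active) > 1:
        h = float(d.min())
        if not np.isfinite(h) or h > cut:
            break
        ties = np.argwhere(d == h)
        _, i, j = min(
            (tuple(sorted((label[a], label[b]))), int(a), int(b))
            for a, b in ties
            if a < b
        )
        # Lance-Williams update for average linkage
        ni, nj = len(clusters[i]), len(clusters[j])
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        clusters[i] = clusters[i] + clusters[j]
        heights[frozenset(clusters[i])] = h
        label[i] = min(label[i], label[j])
        del clusters[j]
        active.remove(j)
        d[j, :] = np.inf
        d[:, j] = np.inf
    return [clusters[i] for i in sorted(active)], heights


def cluster_and_merge(db: Sequence[Pathway], cut: float = 0.15) -> list[MergedPathway]:
    """Merge pathways whose average-linkage distance (1 - overlap rate) is ≤ cut.

    The default cut 0.15 merges clusters whose pairwise overlap averages at
    least 85%.  Singletons pass through as single-member merged pathways with
    height 0.  Output is ordered by the smallest member pathway id.
    """
    if cut < 0:
        raise ValueError("cut must be non-negative")
    if not db:
        return []
    om = overlap_matrix(db)
    clusters, heights = _average_linkage_clusters(om.distance(), om.pathway_ids, cut)
    merged: list[MergedPathway] = []
    for members in clusters:
        member_ids = sorted(db[i].pathway_id for i in members)
        genes = frozenset().union(*(db[i].genes for i in members))
        names = sorted({db[i].name for i in members})
        height = max(
            (h for cl, h in heights.items() if cl <= frozenset(members)), default=0.0
        ) if len(members) > 1 else 0.0
        merged.append(
            MergedPathway(
                merged_id=_merged_id(member_ids) if len(member_ids) > 1 else member_ids[0],
                member_ids=member_ids,
                genes=genes,
                name=" | ".join(names),
                height=height,
            )
        )
    merged.sort(key=lambda m: m.member_ids[0])
    return merged
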