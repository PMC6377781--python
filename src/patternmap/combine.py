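"""Multi-cohort combination: pooled patterns, synchronized genes, region queries.

Several cohorts (tissues, doses, strains — one input file each) can be pooled
once they share a time grid.  Cohorts with different numbers of time points
are first consolidated by averaging groups of adjacent time points.  The
combined view answers two distinct questions:

* pooled pattern groups — how many (cohort, gene) entries follow each
  pattern, a gene counting once per cohort it appears in; and
* synchronized genes — which genes show an *identical* pattern key in every
  cohort (or in at least k of them).

Region queries reproduce Venn-diagram style selections ("significant on days
1, 3 and 21") and stratify the matched genes by their up/down sub-key at the
selected time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import combine_pvalues

from .discretize import DiscretizationRule, PatternGroup, PatternGrouping, group_by_pattern, pattern_key
from .io import CohortTable, ExpressionProfile

__all__ = [
    "DimensionError",
    "CombinedSet",
    "RegionQuery",
    "RegionReport",
    "consolidate_timepoints",
    "combine",
    "pooled_pattern_groups",
    "synchronized_genes",
    "region_counts",
]


class DimensionError(ValueError):
    """Cohorts expose different numbers of time points."""


def consolidate_timepoints(
    table: CohortTable,
    grouping: Sequence[Sequence[int]],
    p_combine: str = "max",
) -> CohortTable:
    """Collapse groups of time points by taking mean log2 fold changes.

    ``grouping`` lists 0-based time-point indices per output time point; it
    must cover every index exactly once in increasing order.  Group p-values
    are combined conservatively as the maximum by default, or by Fisher's
    method with ``p_combine='fisher'``.
    """
    flat = [i for grp in grouping for i in grp]
    if sorted(flat) != list(range(table.T)) or flat != sorted(flat):
        raise ValueError(
            "grouping must cover all time-point indices exactly once, in order"
        )
    if any(not grp for grp in grouping):
        raise ValueError("empty time-point group")
    labels = tuple("+".join(table.timepoints[i] for i in grp) for grp in grouping)
    profiles = []
    for p in table.profiles:
        fc = tuple(sum(p.fc[i] for i in grp) / len(grp) for grp in grouping)
        pv = None
        if p.pvalue is not None:
            if p_combine == "max":
                pv = tuple(max(p.pvalue[i] for i in grp) for grp in grouping)
            elif p_combine == "fisher":
                pv = tuple(
                    p.pvalue[grp[0]]
                    if len(grp) == 1
                    else float(combine_pvalues([p.pvalue[i] for i in grp], method="fisher").pvalue)
                    for grp in grouping
                )
            else:
                raise ValueError(f"unknown p_combine {p_combine!r}")
        profiles.append(
            ExpressionProfile(
                gene_id=p.gene_id, fc=fc, pvalue=pv, entrez=p.entrez,
                symbol=p.symbol, imputed=(),
            )
        )
    return CohortTable(
        cohort_id=table.cohort_id,
        timepoints=labels,
        profiles=profiles,
        source_scale=table.source_scale,
    )


@dataclass
class CombinedSet:
    """Pooled view over cohorts sharing a time grid.

    ``entries`` holds one (cohort_id, gene_id, pattern_key) triple per
    *non-null* profile of every cohort; ``key_maps`` retains every gene's key
    (null included) per cohort for synchronized-gene queries, and
    ``profiles`` back-references the underlying trajectories.
    """

    cohorts: list[CohortTable]
    rule: DiscretizationRule
    entries: list[tuple[str, str, str]]
    key_maps: dict[str, dict[str, str]]
    profiles: dict[tuple[str, str], ExpressionProfile] = field(default_factory=dict)

    @property
    def T(self) -> int:
        return self.cohorts[0].T

    @property
    def cohort_ids(self) -> list[str]:
        return [c.cohort_id for c in self.cohorts]


def combine(
    tables: Sequence[CohortTable],
    rule: DiscretizationRule = DiscretizationRule(),
) -> CombinedSet:
    """Pool two or more cohorts with identical time-point counts."""
    if len(tables) < 2:
        raise ValueError("combine needs at least two cohorts; use the master-panel view for one")
    T = tables[0].T
    for t in tables[1:]:
        if t.T != T:
            raise DimensionError(
                f"cohort {t.cohort_id!r} has {t.T} time points but {tables[0].cohort_id!r} "
                f"has {T}; consolidate time points first"
            )
    ids = [t.cohort_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("cohort IDs must be unique")
    entries: list[tuple[str, str, str]] = []
    key_maps: dict[str, dict[str, str]] = {}
    profiles: dict[tuple[str, str], ExpressionProfile] = {}
    null_key = "0" * T
    for table in tables:
        kmap: dict[str, str] = {}
        for prof in table.profiles:
            key = pattern_key(prof, rule)
            kmap[prof.gene_id] = key
            profiles[(table.cohort_id, prof.gene_id)] = prof
            if key != null_key:
                entries.append((table.cohort_id, prof.gene_id, key))
        key_maps[table.cohort_id] = kmap
    return CombinedSet(
        cohorts=list(tables), rule=rule, entries=entries,
        key_maps=key_maps, profiles=profiles,
    )


def pooled_pattern_groups(combined: CombinedSet) -> PatternGrouping:
    """Pattern groups over pooled (cohort, gene) entries.

    A gene contributes once per cohort, so counts reflect per-cohort
    membership (the per-dose sub-pattern view) rather than unique genes.
    """
    buckets: dict[str, PatternGroup] = {}
    for cohort_id, gene_id, key in combined.entries:
        buckets.setdefault(key, PatternGroup(key)).members.append((cohort_id, gene_id))
    null_count = sum(
        1
        for cid, kmap in combined.key_maps.items()
        for key in kmap.values()
        if set(key) == {"0"}
    )
    groups = [buckets[k] for k in sorted(buckets)]
    return PatternGrouping(groups=groups, null_count=null_count, profiles=dict(combined.profiles))


def synchronized_genes(
    combined: CombinedSet,
    scope: str = "all_cohorts",
    k: int | None = None,
    drop_null: bool = True,
) -> dict[str, list[str]]:
    """Genes whose pattern key is identical across cohorts.

    ``all_cohorts``: the gene must be present in every cohort with the same
    key.  ``at_least_k``: the same key in at least ``k`` cohorts suffices.
    Returns a map pattern key -> sorted gene list.
    """
    n_cohorts = len(combined.cohorts)
    if scope == "all_cohorts":
        need = n_cohorts
    elif scope == "at_least_k":
        if k is None or not 1 <= k <= n_cohorts:
            raise ValueError(f"at_least_k requires 1 <= k <= {n_cohorts}")
        need = k
    else:
        raise ValueError(f"unknown scope {scope!r}")
    null_key = "0" * combined.T
    genes: set[str] = set()
    for kmap in combined.key_maps.values():
        genes.update(kmap)
    out: dict[str, list[str]] = {}
    for gene in sorted(genes):
        keys = [kmap[gene] for kmap in combined.key_maps.values() if gene in kmap]
        if scope == "all_cohorts" and len(keys) < n_cohorts:
            continue
        counts: dict[str, int] = {}
        for key in keys:
            counts[key] = counts.get(key, 0) + 1
        if scope == "all_cohorts":
            if len(counts) == 1:
                (key,) = counts
                if not (drop_null and key == null_key):
                    out.setdefault(key, []).append(gene)
        else:
            for key, c in sorted(counts.items()):
                if c >= need and not (drop_null and key == null_key):
                    out.setdefault(key, []).append(gene)
    return {key: out[key] for key in sorted(out)}


@dataclass(frozen=True)
class RegionQuery:
    """A Venn-region style selection over time points.

    ``constraints`` maps 0-based time-point positions to a required symbol:
    '+', '-', '0', or '*' meaning any significant (non-'0') symbol.  In the
    default ``exact`` mode every position *not* constrained must be '0' —
    the Venn-region semantics; ``at_least`` leaves them unrestricted.
    """

    constraints: Mapping[int, str]
    mode: str = "exact"

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ValueError("a region query needs at least one position constraint")
        for pos, sym in self.constraints.items():
            if sym not in ("+", "-", "0", "*"):
                raise ValueError(f"bad constraint symbol {sym!r} at position {pos}")
        if self.mode not in ("exact", "at_least"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RegionReport:
    """Matched entries of a region query, stratified by sub-key."""

    query: RegionQuery
    matched: list[tuple[str, str, str]]  # (cohort, gene, full key)
    strata: dict[str, list[tuple[str, str]]]  # sub-key -> (cohort, gene)

    @property
    def count(self) -> int:
        return len(self.matched)


def _matches(key: str, query: RegionQuery) -> bool:
    for pos, sym in query.constraints.items():
        if pos >= len(key):
            raise ValueError(f"position {pos} outside the {len(key)}-point time grid")
        if sym == "*":
            if key[pos] == "0":
                return False
        elif key[pos] != sym:
            return False
    if query.mode == "exact":
        for pos, s in enumerate(key):
            if pos not in query.constraints and s != "0":
                return False
    return True


def region_counts(combined: CombinedSet, query: RegionQuery) -> RegionReport:
    """Entries whose keys satisfy a region query, stratified by sub-key.

    The sub-key is the pattern key restricted to the queried positions, in
    increasing position order; the strata partition the matched set.
    """
    positions = sorted(query.constraints)
    matched: list[tuple[str, str, str]] = []
    strata: dict[str, list[tuple[str, str]]] = {}
    for cohort_id, gene_id, key in combined.entries:
        if _matches(key, query):
            matched.append((cohort_id, gene_id, key))
            sub = "".join(key[p] for p in positions)
            strata.setdefault(sub, []).append((cohort_id, gene_id))
    return RegionReport(query=query, matched=matched, strata={k: strata[k] for k in sorted(strata)})
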