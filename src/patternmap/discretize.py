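"""Symbolic discretization of expression profiles and pattern grouping.

Each time point of a profile is mapped to one of three symbols: ``+`` for
significant up-regulation (log2 fold change at or above the threshold, with
the p-value gate passed when p-values are present), ``-`` for significant
down-regulation, and ``0`` otherwise.  Concatenating the symbols yields the
*pattern key* (e.g. ``++-`` = up, up, down), and genes sharing a key form a
pattern group — the unit of display, selection and enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import CohortTable, ExpressionProfile

ALPHABET = ("+", "-", "0")
# ASCII order '+' < '-' < '0' matches the declared symbol collation, so plain
# string comparison breaks ties deterministically.

__all__ = [
    "ALPHABET",
    "DiscretizationRule",
    "PatternGroup",
    "PatternGrouping",
    "discretize",
    "pattern_key",
    "group_by_pattern",
    "sort_groups",
    "stage_filter",
]


@dataclass(frozen=True)
class DiscretizationRule:
    """Thresholds mapping (fold change, p-value) to a symbol.

    fc_threshold is a log2 magnitude; the default 1.0 is the conventional
    two-fold cutoff.  When p_threshold is None (or a profile carries no
    p-values) significance is judged on fold change alone.  p_direction
    exists because input DEG lists occasionally state the p filter in the
    opposite direction; "less" (p < threshold is significant) is the default.
    """

    fc_threshold: float = 1.0
    p_threshold: float | None = 0.05
    p_direction: str = "less"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be positive")
        if self.p_threshold is not None and not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.p_direction not in ("less", "greater"):
            raise ValueError("p_direction must be 'less' or 'greater'")


def _p_gate(p: float | None, rule: DiscretizationRule) -> bool:
    if p is None or rule.p_threshold is None:
        return True
    return p < rule.p_threshold if rule.p_direction == "less" else p > rule.p_threshold


def discretize(fc_log2: float, p: float | None, rule: DiscretizationRule) -> str:
    """Map one (log2 fold change, optional p-value) observation to '+', '-' or '0'."""
    if not math.isfinite(fc_log2):
        raise ValueError(f"non-finite fold change {fc_log2!r}")
    if p is not None and not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p!r} outside [0, 1]")
    if _p_gate(p, rule):
        if fc_log2 >= rule.fc_threshold:
            return "+"
        if fc_log2 <= -rule.fc_threshold:
            return "-"
    return "0"


def pattern_key(profile: ExpressionProfile, rule: DiscretizationRule) -> str:
    """Concatenate the per-time-point symbols of a profile into its pattern key."""
    T = len(profile.fc)
    if T < 2:
        raise ValueError("profiles need at least two time points")
    ps = profile.pvalue if profile.pvalue is not None else (None,) * T
    return "".join(discretize(profile.fc[t], ps[t], rule) for t in range(T))


@dataclass
class PatternGroup:
    """A pattern key with its member (cohort, gene) entries."""

    key: str
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)

    def is_null(self) -> bool:
        return set(self.key) == {"0"}


@dataclass
class PatternGrouping:
    """Partition of a cohort's (or combined set's) profiles by pattern key.

    When the all-'0' group is dropped its size is still reported via
    ``null_count`` so the partition accounting stays exact.  ``profiles``
    back-references every member's profile for trend decomposition.
    """

    groups: list[PatternGroup]
    null_count: int
    profiles: dict[tuple[str, str], ExpressionProfile] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(g.count for g in self.groups) + self.null_count

    def group(self, key: str) -> PatternGroup:
        for g in self.groups:
            if g.key == key:
                return g
        raise KeyError(key)


def group_by_pattern(
    table: CohortTable,
    rule: DiscretizationRule = DiscretizationRule(),
    drop_null: bool = True,
) -> PatternGrouping:
    """Partition a cohort's profiles into pattern groups.

    With ``drop_null`` (default) the uninformative all-'0' group is excluded
    from the group list; its size is returned as ``null_count``.
    """
    buckets: dict[str, PatternGroup] = {}
    profiles: dict[tuple[str, str], ExpressionProfile] = {}
    for prof in table.profiles:
        key = pattern_key(prof, rule)
        buckets.setdefault(key, PatternGroup(key)).members.append((table.cohort_id, prof.gene_id))
        profiles[(table.cohort_id, prof.gene_id)] = prof
    null_key = "0" * table.T
    null_count = 0
    if drop_null and null_key in buckets:
        null_count = buckets.pop(null_key).count
    groups = [buckets[k] for k in sorted(buckets)]
    return PatternGrouping(groups=groups, null_count=null_count, profiles=profiles)


def sort_groups(groups: Iterable[PatternGroup], by: str = "count_desc") -> list[PatternGroup]:
    """Order groups by descending member count (ties: key collation) or by key."""
    groups = list(groups)
    if by == "count_desc":
        return sorted(groups, key=lambda g: (-g.count, g.key))
    if by == "key_lex":
        return sorted(groups, key=lambda g: g.key)
    raise ValueError(f"unknown sort order {by!r}")


def stage_filter(
    groups: Iterable[PatternGroup], stage: str, rule: DiscretizationRule | None = None
) -> list[PatternGroup]:
    """Select early- or late-responsive pattern groups.

    Early: the first significant (non-'0') symbol falls in the first
    ceil(T/2) time points; late: in the remaining ones.  All-'0' keys are
    never returned.
    """
    if stage not in ("early", "late"):
        raise ValueError("stage must be 'early' or 'late'")
    out = []
    for g in groups:
        first = next((i for i, s in enumerate(g.key) if s != "0"), None)
        if first is None:
            continue
        cut = math.ceil(len(g.key) / 2)
        if (stage == "early") == (first < cut):
            out.append(g)
    return out
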