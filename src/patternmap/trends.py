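"""Trend decomposition: direction of expression change across time.

Two genes can share a pattern key yet behave very differently: linear fold
changes (2, 3, 4) and (5, 4, 3) are both significantly up at every time point
(pattern ``+++``), but the first rises while the second falls.  The *trend
key* captures the sign of the change between adjacent time points, splitting
each pattern group into sub-groups with a common temporal shape.

Two alphabet-length conventions are supported:

``diff_only``
    one symbol per adjacent pair — sign(fc[t+1] - fc[t]) — giving T-1 symbols;
``baseline_inclusive`` (default)
    the change from the no-change baseline (sign of fc[1]) followed by the
    T-1 difference symbols, giving one symbol per time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .discretize import PatternGroup
from .io import ExpressionProfile

__all__ = ["TrendGroup", "trend_key", "group_by_trend", "trend_members_by_cohort"]


@dataclass
class TrendGroup:
    """A trend key within a parent pattern group."""

    parent: str
    key: str
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.members)


def _sign(delta: float, zero_band: float) -> str:
    if abs(delta) <= zero_band:
        return "0"
    return "+" if delta > 0 else "-"


def trend_key(
    profile: ExpressionProfile,
    mode: str = "baseline_inclusive",
    zero_band: float = 0.0,
) -> str:
    """Symbol string of expression-change directions for one profile (log2 scale)."""
    if zero_band < 0:
        raise ValueError("zero_band must be non-negative")
    fc = profile.fc
    if len(fc) < 2:
        raise ValueError("profiles need at least two time points")
    for v in fc:
        if not math.isfinite(v):
            raise ValueError(f"non-finite fold change {v!r}")
    diffs = "".join(_sign(fc[t + 1] - fc[t], zero_band) for t in range(len(fc) - 1))
    if mode == "diff_only":
        return diffs
    if mode == "baseline_inclusive":
        return _sign(fc[0], zero_band) + diffs
    raise ValueError(f"unknown trend mode {mode!r}")


def group_by_trend(
    group: PatternGroup,
    profiles: Mapping[tuple[str, str], ExpressionProfile],
    mode: str = "baseline_inclusive",
    zero_band: float = 0.0,
    sort: str = "count_desc",
) -> list[TrendGroup]:
    """Partition a pattern group's members by trend key.

    ``profiles`` is the back-reference map produced by
    :func:`patternmap.discretize.group_by_pattern`.
    """
    buckets: dict[str, TrendGroup] = {}
    for member in group.members:
        try:
            prof = profiles[member]
        except KeyError:
            raise KeyError(f"member {member} has no profile in the lookup") from None
        key = trend_key(prof, mode=mode, zero_band=zero_band)
        buckets.setdefault(key, TrendGroup(parent=group.key, key=key)).members.append(member)
    trends = list(buckets.values())
    if sort == "count_desc":
        trends.sort(key=lambda t: (-t.count, t.key))
    else:
        trends.sort(key=lambda t: t.key)
    return trends


def trend_members_by_cohort(trend: TrendGroup) -> dict[str, list[str]]:
    """Split a trend group's members per cohort (e.g. per dose or tissue)."""
    out: dict[str, list[str]] = {}
    for cohort_id, gene_id in trend.members:
        out.setdefault(cohort_id, []).append(gene_id)
    return out
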