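"""Split one expression pattern into trends (direction of change over time).

Two genes with linear fold changes (2, 3, 4) and (5, 4, 3) are both
significantly up at every time point — the same primary pattern '+++' — yet
one rises while the other falls.  Trend keys separate them.
"""

import math

from patternmap import (
    CohortTable,
    DiscretizationRule,
    ExpressionProfile,
    group_by_pattern,
    group_by_trend,
    trend_key,
)

rising = ExpressionProfile("rising", tuple(math.log2(v) for v in (2, 3, 4)), (0.01,) * 3)
falling = ExpressionProfile("falling", tuple(math.log2(v) for v in (5, 4, 3)), (0.01,) * 3)
table = CohortTable("demo", ("T1", "T2", "T3"), [rising, falling])

rule = DiscretizationRule()
grouping = group_by_pattern(table, rule)
(group,) = grouping.groups
print(f"primary pattern {group.key}: {group.count} genes (both profiles)")

for mode in ("diff_only", "baseline_inclusive"):
    print(f"\ntrend keys ({mode}):")
    for prof in (rising, falling):
        print(f"  {prof.gene_id:8s} -> {trend_key(prof, mode)}")
    trends = group_by_trend(group, grouping.profiles, mode=mode)
    print("  trend groups:", {t.key: t.count for t in trends})

# diff_only gives one symbol per adjacent pair: '++' = increasing at both
# steps, '--' = decreasing.  baseline_inclusive prepends the change from the
# no-change baseline, so 'falling' becomes '+--': a spike above baseline
# followed by a steady decline.  One pattern, two clearly different behaviours.
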