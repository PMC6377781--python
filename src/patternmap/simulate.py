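"""Seeded generators for cohort tables and pathway databases with known structure.

These generators plant exactly the structure the analysis is meant to
recover: cohort tables whose profiles discretize to requested pattern keys,
and GMT databases whose pairwise overlap rates hit requested targets.  They
emulate precomputed differential-expression statistics (log2 fold changes
and p-values per time point), not raw counts — matching the input the
pipeline consumes — and are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .discretize import ALPHABET, DiscretizationRule
from .io import CohortTable, ExpressionProfile, Pathway

__all__ = ["PlantSpec", "generate_cohort", "generate_gmt"]


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for a cohort with planted pattern structure.

    For each requested pattern key, ``patterns[key]`` genes are generated
    whose discretization under a rule with ``fc_threshold`` / ``p_threshold``
    reproduces exactly that key.  Significant positions sit at
    ``±fc_magnitude`` log2 with a small jitter; neutral positions are drawn
    uniformly from the middle half of the neutral band; p-values come from
    ``p_significant`` or ``p_null`` ranges accordingly.
    """

    seed: int
    T: int
    patterns: Mapping[str, int]
    fc_magnitude: float = 1.5
    jitter: float = 0.2
    fc_threshold: float = 1.0
    p_threshold: float = 0.05
    p_significant: tuple[float, float] = (1e-5, 0.01)
    p_null: tuple[float, float] = (0.2, 0.9)
    with_pvalues: bool = True
    gene_prefix: str = "gene"

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be at least 2")
        for key in self.patterns:
            if len(key) != self.T:
                raise ValueError(f"pattern {key!r} has length {len(key)}, expected T={self.T}")
            if any(s not in ALPHABET for s in key):
                raise ValueError(f"pattern {key!r} uses symbols outside {ALPHABET}")
        if any(c < 0 for c in self.patterns.values()):
            raise ValueError("pattern counts must be non-negative")
        if self.fc_magnitude - self.jitter <= self.fc_threshold:
            raise ValueError(
                f"fc_magnitude {self.fc_magnitude} minus jitter {self.jitter} does not "
                f"clear the threshold {self.fc_threshold}; planted symbols would be unstable"
            )
        if not (0 < self.p_significant[0] <= self.p_significant[1] < self.p_threshold):
            raise ValueError("p_significant range must sit strictly below p_threshold")
        if not (self.p_threshold < self.p_null[0] <= self.p_null[1] <= 1):
            raise ValueError("p_null range must sit strictly above p_threshold")

    def rule(self) -> DiscretizationRule:
        return DiscretizationRule(
            fc_threshold=self.fc_threshold,
            p_threshold=self.p_threshold if self.with_pvalues else None,
        )


def generate_cohort(spec: PlantSpec, cohort_id: str = "sim") -> CohortTable:
    """Generate a cohort whose pattern grouping recovers ``spec.patterns`` exactly."""
    rng = np.random.default_rng(spec.seed)
    profiles: list[ExpressionProfile] = []
    counter = 0
    for key in sorted(spec.patterns):
        for _ in range(spec.patterns[key]):
            counter += 1
            fc: list[float] = []
            pv: list[float] = []
            for sym in key:
                if sym == "0":
                    fc.append(float(rng.uniform(-0.5, 0.5) * spec.fc_threshold))
                    pv.append(float(rng.uniform(*spec.p_null)))
                else:
                    mag = spec.fc_magnitude + float(rng.uniform(-spec.jitter, spec.jitter))
                    fc.append(mag if sym == "+" else -mag)
                    pv.append(float(rng.uniform(*spec.p_significant)))
            gid = f"{spec.gene_prefix}{counter:05d}"
            profiles.append(
                ExpressionProfile(
                    gene_id=gid,
                    fc=tuple(fc),
                    pvalue=tuple(pv) if spec.with_pvalues else None,
                    symbol=gid.upper(),
                )
            )
    return CohortTable(
        cohort_id=cohort_id,
        timepoints=tuple(f"T{i + 1}" for i in range(spec.T)),
        profiles=profiles,
    )


def _required_intersection(size_a: int, size_b: int, rate: float) -> int:
    """Invert the overlap rate: |a ∩ b| making min/|a ∪ b| hit ``rate``."""
    m = size_a + size_b - min(size_a, size_b) / rate
    return int(round(m))


def generate_gmt(
    seed: int,
    n_pathways: int,
    size_range: tuple[int, int] = (10, 40),
    overlap_plan: Sequence[tuple[int, int, float]] = (),
    gene_prefix: str = "PWG",
) -> list[Pathway]:
    """Generate a pathway database with controlled pairwise overlap rates.

    ``overlap_plan`` lists (i, j, target_rate) for 0-based pathway indices;
    each planned pair shares exactly the intersection size that realizes the
    target under the overlap-rate formula (achieved rate within 0.02 of the
    target, or the plan is rejected as infeasible).  Unplanned pathways draw
    disjoint gene blocks, so their pairwise overlap stays at the disjoint
    floor.  A pathway may appear in at most one planned pair.
    """
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError("bad size_range")
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_pathways)]

    planned: dict[int, tuple[int, int]] = {}  # index -> (pair index, intersection)
    seen: set[int] = set()
    for i, j, rate in overlap_plan:
        if not (0 <= i < n_pathways and 0 <= j < n_pathways and i != j):
            raise ValueError(f"bad plan pair ({i}, {j})")
        if i in seen or j in seen:
            raise ValueError("a pathway may appear in at most one planned pair")
        if not 0 < rate <= 1:
            raise ValueError(f"target overlap rate {rate} outside (0, 1]")
        m = _required_intersection(sizes[i], sizes[j], rate)
        if not 0 <= m <= min(sizes[i], sizes[j]):
            raise ValueError(
                f"target rate {rate} infeasible for sizes {sizes[i]}/{sizes[j]}"
            )
        achieved = min(sizes[i], sizes[j]) / (sizes[i] + sizes[j] - m)
        if abs(achieved - rate) > 0.02:
            raise ValueError(
                f"target rate {rate} not achievable within 0.02 for sizes "
                f"{sizes[i]}/{sizes[j]} (closest {achieved:.3f})"
            )
        planned[i] = (j, m)
        planned[j] = (i, m)
        seen.update((i, j))

    next_gene = 1

    def take(n: int) -> list[str]:
        nonlocal next_gene
        out = [f"{gene_prefix}{g:05d}" for g in range(next_gene, next_gene + n)]
        next_gene += n
        return out

    genes: dict[int, list[str]] = {}
    done: set[int] = set()
    for idx in range(n_pathways):
        if idx in done:
            continue
        if idx in planned:
            j, m = planned[idx]
            shared = take(m)
            genes[idx] = shared + take(sizes[idx] - m)
            genes[j] = shared + take(sizes[j] - m)
            done.update((idx, j))
        else:
            genes[idx] = take(sizes[idx])
            done.add(idx)

    return [
        Pathway(
            pathway_id=f"PW{idx + 1:03d}",
            name=f"synthetic pathway {idx + 1}",
            genes=frozenset(genes[idx]),
            source="synthetic",
        )
        for idx in range(n_pathways)
    ]
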