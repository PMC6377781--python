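"""One-sided hypergeometric pathway enrichment for selected gene groups.

Any gene selection produced upstream — a pattern group, a trend sub-group, a
synchronized-gene list or a region query result — can be tested against a
pathway database.  For a universe of N genes containing K pathway members, a
query of n genes overlapping the pathway in k is scored by the upper tail
P(X >= k) of the hypergeometric distribution, i.e. the probability of drawing
at least k pathway genes by chance.  P-values are adjusted across the tested
pathways (Benjamini-Hochberg by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import Pathway
from .pathways import MergedPathway

__all__ = [
    "EnrichmentResult",
    "EnrichmentRun",
    "hypergeom_upper_tail",
    "enrich",
    "adjust_pvalues",
]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: pathway genes in the universe, n: query size,
    k: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def adjust_pvalues(ps: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``BH`` = Benjamini-Hochberg step-up FDR, ``bonferroni``, or ``none``.
    """
    ps = list(ps)
    if not ps:
        return []
    if any(not 0 < p <= 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return ps
    if method == "BH":
        return list(multipletests(ps, method="fdr_bh")[1])
    if method == "bonferroni":
        return list(multipletests(ps, method="bonferroni")[1])
    raise ValueError(f"unknown adjustment method {method!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric test record for one pathway against one gene group."""

    pathway_id: str
    name: str
    k: int  # query genes in the pathway
    K: int  # pathway size within the universe
    n: int  # query size within the universe
    N: int  # universe size
    p: float
    q: float  # adjusted p
    members_hit: tuple[str, ...] = ()


@dataclass
class EnrichmentRun:
    """Outcome of one enrichment call, including what was *not* tested.

    ``status`` is "ok" or "empty_intersection" (the query shares no genes
    with the universe — reported explicitly rather than as zero rows).
    ``untested`` lists pathways with no overlap with the query (k = 0).
    """

    results: list[EnrichmentResult]
    untested: list[str]
    universe_size: int
    query_size: int
    universe_label: str
    correction: str
    status: str = "ok"


def _norm(genes: Iterable[str]) -> dict[str, str]:
    # case-insensitive matching: map uppercased id -> first-seen original
    out: dict[str, str] = {}
    for g in genes:
        out.setdefault(g.upper(), g)
    return out


def enrich(
    query_genes: Iterable[str],
    db: Sequence[Pathway | MergedPathway],
    universe: str | Iterable[str] = "db_union",
    measured_genes: Iterable[str] | None = None,
    correction: str = "BH",
) -> EnrichmentRun:
    """Test every pathway of ``db`` for over-representation in ``query_genes``.

    ``universe`` is ``"db_union"`` (all genes in the database), ``"measured"``
    (the measured genes intersected with the database universe — requires
    ``measured_genes``), or an explicit gene collection.  Gene identifiers
    match case-insensitively.  Results are sorted by adjusted p, then raw p,
    then pathway id; pathways with no query overlap are listed as untested.
    """
    db_union = set()
    for pw in db:
        db_union.update(g.upper() for g in pw.genes)
    if isinstance(universe, str):
        if universe == "db_union":
            uni = db_union
            label = "db_union"
        elif universe == "measured":
            if measured_genes is None:
                raise ValueError("universe='measured' requires measured_genes")
            uni = {g.upper() for g in measured_genes} & db_union
            label = "measured∩db"
        else:
            raise ValueError(f"unknown universe {universe!r}")
    else:
        uni = {g.upper() for g in universe}
        label = "custom"

    qnorm = _norm(query_genes)
    query = set(qnorm) & uni
    if not query:
        return EnrichmentRun(
            results=[], untested=[pw_id(pw) for pw in db],
            universe_size=len(uni), query_size=0,
            universe_label=label, correction=correction,
            status="empty_intersection",
        )

    N, n = len(uni), len(query)
    rows: list[tuple[Pathway | MergedPathway, int, int, tuple[str, ...]]] = []
    untested: list[str] = []
    for pw in db:
        pw_genes = {g.upper() for g in pw.genes} & uni
        hit = query & pw_genes
        if not hit:
            untested.append(pw_id(pw))
            continue
        rows.append((pw, len(hit), len(pw_genes), tuple(sorted(qnorm[g] for g in hit))))
    ps = [hypergeom_upper_tail(k, N, K, n) for _, k, K, _ in rows]
    qs = adjust_pvalues(ps, method=correction)
    results = [
        EnrichmentResult(
            pathway_id=pw_id(pw), name=pw.name, k=k, K=K, n=n, N=N,
            p=p, q=q, members_hit=hit,
        )
        for (pw, k, K, hit), p, q in zip(rows, ps, qs)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.pathway_id))
    return EnrichmentRun(
        results=results, untested=untested, universe_size=N, query_size=n,
        universe_label=label, correction=correction,
    )


def pw_id(pw: Pathway | MergedPathway) -> str:
    return pw.pathway_id if isinstance(pw, Pathway) else pw.merged_id
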