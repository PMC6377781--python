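# Methods

## The model: symbolic representation of expression trajectories

The package analyses precomputed time-series differential-expression
statistics: for each gene, a fold change (and optionally a p-value) per time
point, comparing treatment to control.  Rather than fitting a parametric
curve, each trajectory is discretized into a three-letter alphabet and
handled as a string:

* `+` — significantly up at that time point: log2 fold change ≥ `fc_threshold`
  and, when p-values are present, p < `p_threshold`;
* `-` — significantly down (log2 FC ≤ −`fc_threshold`, same p gate);
* `0` — everything else.

Concatenating the symbols yields the **pattern key** (`++-` = up, up, down).
Grouping genes by key is exact and assumption-free: it finds every distinct
pattern present in the data instead of a fixed number of smoothed clusters,
at the cost of ignoring magnitude beyond the thresholds.  Both threshold
comparisons are inclusive.  When the p-value gate fails, the symbol is `0`
regardless of fold change.

All fold changes are held internally in log2 (0 = no change).  Signed-linear
input (2 = two-fold up, −2 = two-fold down) is converted at parse time:
v ≥ 1 → log2 v, v ≤ −1 → −log2(−v), 0 → 0.  Signed-linear values strictly
inside (−1, 1) are contradictory under this convention and the row is
rejected with a report (never silently dropped: parsed + rejected = rows
read).  A single canonical scale keeps every downstream rule — thresholds,
trend signs, time-point means — unambiguous.

### Trends

Genes sharing a pattern can behave differently (fold changes 2,3,4 versus
5,4,3 are both `+++`).  The **trend key** records the sign of the change
between adjacent time points.  Two conventions are exposed because both are
useful and they answer slightly different questions:

* `diff_only` — T−1 symbols, sign(fc[t+1] − fc[t]); invariant under adding a
  constant to the whole profile.
* `baseline_inclusive` (default) — prepends the change from the no-change
  baseline, sign(fc[1] − 0), giving one symbol per time point; this
  distinguishes a spike-then-decline (`+--`) from a decline from baseline
  (`---`).

`zero_band` (default 0, log2 units) treats |Δ| ≤ band as flat, to absorb
numerical noise in inputs with many near-identical values.

### Stage filters

Early-responsive patterns have their first non-`0` symbol within the first
⌈T/2⌉ time points; late-responsive ones in the remainder.  All-`0` keys are
excluded from both.

## Multi-cohort combination

Cohorts must share a time-point count; differing grids are consolidated
first by averaging user-specified groups of adjacent time points (log2
means).  Group p-values are combined as the maximum by default — a
deliberately conservative choice, since the mean rule is defined for the
values, not the significances — with Fisher's method available.
Consolidating with singleton groups is the identity.

Two distinct multi-cohort semantics are provided as separate operations
rather than one hybrid:

* **pooled pattern groups** count (cohort, gene) entries, so a gene present
  in three cohorts contributes three entries — this is the per-dose /
  per-tissue membership view;
* **synchronized genes** require an identical pattern key in every cohort
  (or in ≥ k cohorts), the strict per-gene view.

Region queries select entries significant at chosen time points (`exact`
mode: and nowhere else — Venn-region semantics; `at_least` mode relaxes
this) and stratify matches by the sub-key restricted to those positions.
The strata always partition the matched set.

## Pathway database trimming and merging

Databases aggregated from several resources contain near-duplicates and
very large catch-all sets.  Sets larger than `max_size` (default 1000; the
intent is "thousands of genes") or smaller than `min_size` (default 3) are
removed first.  Similarity of two gene sets is the overlap rate

    overlap(A, B) = min(|A|, |B|) / |A ∪ B|

which is 1 exactly when the sets are identical and rewards nesting: a small
pathway fully contained in a larger one scores |A|/|B|, higher than its
Jaccard index.  Note the disjoint floor is not 0 — two disjoint equal-size
sets score 0.5 — which is why the merge cut must be interpreted on the
distance d = 1 − overlap, not as "any positive similarity".

Pathways are clustered by average linkage on d and every cluster with merge
heights ≤ `cut` (default 0.15, i.e. ≥ 85% average overlap) becomes one
merged pathway carrying the union gene set, the member ids, and the largest
merge height in the cluster; singletons pass through unchanged, so the gene
universe is conserved exactly.

The agglomeration is implemented in-package with the Lance–Williams average
update and an explicit deterministic tie-break: among pairs at the minimal
distance, merge the pair whose smallest member identifiers compare lowest.
Flat clusters under average linkage are genuinely tie-sensitive, and
overlap distances tie often (every disjoint equal-size pair sits at 0.5), so
a fixed tie order is required for reproducible merged databases.  Average
linkage is monotone (no inversions), so agglomerating until the minimal
distance exceeds the cut yields exactly the dendrogram's flat clusters at
that height.  The test suite cross-checks the implementation against both an
exhaustive recompute-everything agglomeration and scipy's
`linkage`/`fcluster` on tie-free inputs.

## Enrichment

For a gene group of size n drawn from a universe of N genes of which K
belong to a pathway, the enrichment statistic is the one-sided
hypergeometric upper tail P(X ≥ k) of the observed overlap k (computed via
`scipy.stats.hypergeom.sf`, which is stable in log space).  Pathways with
k = 0 are reported as untested rather than given p = 1 rows.  P-values are
Benjamini–Hochberg adjusted by default (Bonferroni and no correction are
available); results sort by adjusted p, raw p, then pathway id.

The universe defaults to the measured genes intersected with the database's
gene union — the statistically defensible choice, since genes that could
never be drawn should not inflate N — with `db_union` as the fallback when
no cohort is loaded and explicit custom universes supported.  The universe
choice and correction method are echoed in every export.  Gene identifiers
match case-insensitively; no aliasing or fuzzy matching is attempted.

## Synthetic data

The generators emulate the *input* the pipeline consumes — per-time-point
log2 fold changes and p-values with a known discretization — not raw
counts.  Defaults: significant positions at ±1.5 log2 with uniform ±0.2
jitter (clearing the 1.0 threshold with margin), significant p-values
uniform in [1e-5, 0.01], neutral positions uniform in ±0.5·threshold with
p in [0.2, 0.9].  Recipe validation rejects any parameterization whose noise
could cross a threshold, so planted patterns are recovered exactly by
construction — which is the point: the generators test the machinery, not
the biology.  Consequently, passing recovery tests says nothing about
behaviour on noisy real data near the thresholds, where discretization is
intentionally sharp; there is no gene–gene correlation, no dropout, and no
magnitude structure beyond the planted symbols.

GMT generation inverts the overlap-rate formula to find the integer
intersection realizing a target rate (achieved within 0.02 or rejected as
infeasible); unplanned pathways draw disjoint gene blocks.

## Numerical and design choices

* Symbols are ASCII `+`, `-`, `0`; their ASCII order is also the declared
  collation for count ties and lexicographic sorts, so sorted outputs are
  reproducible byte-for-byte.
* Exports write floats at 6 significant digits with a provenance comment
  (tool version, config hash); identical inputs give identical bytes.
* `count_desc` sorting breaks ties by key collation; merged pathways order
  by smallest member id; enrichment by (q, p, id).
* The all-`0` pattern group is dropped from displays by default but its
  size is always reported, keeping the partition accounting exact.
* Problem sizes in tests and the acceptance script (universes ≤ 60 genes,
  databases ≤ 10 pathways, ≤ 50 planted-recovery seeds, hypergeometric
  enumeration up to N = 30) were chosen as the smallest sizes that still
  exercise every code path and tie case; all results are exact or
  oracle-checked at these sizes, so larger inputs add cost, not coverage.

## Known limitations

* The discretization is hard-threshold: a gene at 1.99-fold is `0`, at
  2.00-fold `+`.  No borderline handling is attempted beyond the optional
  trend `zero_band`.
* Cohorts must share a gene identifier namespace; no ortholog or alias
  mapping.
* No ranked (GSEA-style) enrichment and no ontology-topology correction.
* Time-point consolidation averages log2 fold changes; it does not model
  within-group variance.
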