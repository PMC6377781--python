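# patternmap

Symbolic pattern analysis of time-series differential expression, for
transcriptomics (and other omics) experiments with multiple tissues, doses
or conditions measured over time.

Time-series designs pose three recurring questions: which temporal patterns
do most genes follow, which genes follow an *identical* pattern across
cohorts, and which biological functions underlie each pattern.  `patternmap`
answers them by discretizing each gene's trajectory of fold changes into a
three-symbol string and treating the strings as exact cluster keys:

* `+` if log2 FC ≥ θ (linear two-fold by default) and p < 0.05 when
  p-values are given; `-` if log2 FC ≤ −θ; `0` otherwise.  The concatenated
  **pattern key** (`++-` = up, up, down) partitions the genes exactly — no
  smoothing, no preset cluster count.
* Each pattern splits into **trends**, the signs of the change between
  adjacent time points, separating e.g. rising from falling genes that share
  a pattern.
* Cohorts sharing a time grid combine into pooled pattern groups,
  **synchronized gene** lists (identical key in every cohort), and
  Venn-style **region queries** stratified by up/down sub-keys.
* Pathway databases (GMT) are deduplicated by clustering on the overlap
  rate min(|A|,|B|)/|A∪B| with average linkage (merge at distance
  1 − overlap ≤ 0.15, i.e. ≥ 85% overlap), and any gene group is tested for
  enrichment with the one-sided hypergeometric upper tail
  P(X ≥ k | N, K, n), Benjamini–Hochberg adjusted.

Inputs are tab-delimited DEG tables (ID, optional Entrez/Symbol, per-time
point optional P and FC columns) and standard GMT files; every result is
exported as stable TSV/JSON.  See `docs/methods.md` for the full model
description and design choices.

## Worked example

`examples/trend_breakdown.py` runs the canonical two-gene example — linear
fold changes (2, 3, 4) and (5, 4, 3) across three time points, both
significant everywhere:

```
primary pattern +++: 2 genes (both profiles)

trend keys (diff_only):
  rising   -> ++
  falling  -> --
  trend groups: {'++': 1, '--': 1}

trend keys (baseline_inclusive):
  rising   -> +++
  falling  -> +--
  trend groups: {'+++': 1, '+--': 1}
```

Both genes land in the same primary pattern `+++` (significantly up at
every time point), but their trends differ: one rises step by step (`++`),
the other declines (`--`); in baseline-inclusive form the decliner reads
`+--` — a spike above baseline followed by a steady fall.  The other
scripts in `examples/` demonstrate pattern grouping, multi-cohort
combination, pathway merging and enrichment the same way, each printing the
numbers it computes and what they mean.

A thin CLI wraps the library for shell use:

```sh
patternmap simulate --seed 1 --timepoints 3 --pattern '+0-=5' --out-dir demo
patternmap patterns demo/sim.tsv --fc-scale log2 --out-dir demo
patternmap merge-db db.gmt --cut 0.15 --out-dir demo
patternmap enrich demo/merged.gmt --genes query.txt --out-dir demo
```

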