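"""Hypergeometric enrichment of a pattern group against a pathway database.

Plants a pattern group whose genes are exactly one pathway's members, runs
the one-sided hypergeometric test over the whole database and shows that
the planted pathway ranks first.
"""

from patternmap import enrich, generate_gmt, hypergeom_upper_tail

db = generate_gmt(seed=2, n_pathways=6, size_range=(12, 20))
target = db[2]
query = sorted(target.genes)[:10]  # a gene group overlapping pathway 3 in 10 genes

run = enrich(query, db, universe="db_union")
print(f"universe N={run.universe_size}, query n={run.query_size} "
      f"({run.correction}-adjusted)")
for r in run.results:
    print(f"  {r.pathway_id}: k={r.k}/K={r.K}  p={r.p:.3e}  q={r.q:.3e}")
print(f"untested (no overlap): {len(run.untested)} pathways")

p = hypergeom_upper_tail(k=run.results[0].k, N=run.results[0].N,
                         K=run.results[0].K, n=run.results[0].n)
print(f"\ntop hit recomputed directly: P(X >= {run.results[0].k}) = {p:.3e}")

# p is the chance of drawing at least k pathway genes in a random query of
# size n from the N-gene universe containing K pathway genes.  Only the
# planted pathway overlaps the query, so it is the single tested pathway and
# its upper-tail probability is tiny.
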