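"""Generate a synthetic diagnostic cohort and rank genes by cutpoint F1.

Builds a 21-vs-40 cohort (the shape of an NDBE-vs-LGD comparison) with
10 planted discriminative genes, then searches each gene's F1-optimal
expression cutpoint and ranks all genes.  With a 2 log2-unit planted
shift the planted genes should dominate the top of the ranking.
"""

from bepanel import SyntheticConfig, generate_cohort, rank_genes

cfg = SyntheticConfig(
    n_neg=21, n_pos=40, n_genes=500, n_discriminative=10,
    effect_size=2.0, noise_sd=1.0, seed=7,
)
matrix, annotation, truth = generate_cohort(cfg)
print(f"cohort: {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"({len(truth.discriminative_genes)} planted)")

ranked = rank_genes(matrix, annotation)
top = ranked.head(10)
print("\ntop 10 genes by cutpoint F1 (planted marked *):")
for _, row in top.iterrows():
    star = "*" if row["gene_id"] in truth.discriminative_genes else " "
    print(f"  {star} {row['gene_id']}  F1={row['f1']:.3f}  AUC={row['auc']:.3f}  "
          f"cut={row['cutpoint']:+.2f} ({row['direction']})")

n_hit = sum(g in truth.discriminative_genes for g in top["gene_id"])
print(f"\n{n_hit}/10 of the top-ranked genes are planted biomarkers; "
      "each F1 is the best achievable by a single expression threshold.")
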