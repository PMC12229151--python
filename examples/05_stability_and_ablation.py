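"""Repeated-run stability and decremental feature ablation.

Re-runs the LOOCV evaluation of one fixed model under many oversampling
random states (the only stochastic component) to get mean ± SD per
metric, then shrinks the panel one size at a time, evaluating all
subsets per size, to see how performance decays with fewer genes.
"""

from bepanel import (
    ModelSpec,
    SyntheticConfig,
    decremental_ablation,
    generate_cohort,
    repeated_runs,
)

cfg = SyntheticConfig(
    n_neg=21, n_pos=40, n_genes=60, n_discriminative=6,
    effect_size=1.5, noise_sd=1.0, seed=4,
)
matrix, annotation, truth = generate_cohort(cfg)
genes = tuple(sorted(truth.discriminative_genes))

spec = ModelSpec(family="linear_svm", genes=genes)
summary = repeated_runs(matrix, annotation, spec, n_runs=25, base_seed=0)
print(f"linear SVM on {len(genes)} genes, 25 repeated LOOCV runs:")
for m in ("accuracy", "recall", "precision", "f1", "specificity"):
    print(f"  {m:12s} {summary.metric_mean[m]:.3f} +/- {summary.metric_sd[m]:.3f}")
c = summary.mean_counts
print(f"  mean counts  TP={c.tp:.2f} FP={c.fp:.2f} TN={c.tn:.2f} FN={c.fn:.2f}")

curve = decremental_ablation(matrix, annotation, "linear_svm", list(genes),
                             seed=0, subset_cap=30)
print("\nablation (median F1 by panel size):")
for k, row in curve.iterrows():
    print(f"  k={k}: F1 {row['f1_median']:.3f} +/- {row['f1_sd']:.3f} "
          f"over {int(row['n_subsets'])} subsets")
print("\nSmall SDs across runs mean the oversampling randomness barely moves "
      "the metrics;\nthe ablation curve shows how many genes the signature "
      "can lose before performance drops.")
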