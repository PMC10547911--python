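"""End-to-end run: preprocess, select genes, cluster, evaluate.

With K given, the final clustering is K-means on the selected genes; with
K omitted the cluster count is estimated by Louvain community detection on
a k-nearest-neighbor graph.
"""

from scfse import FixtureSpec, FsqssaConfig, generate, run_pipeline

cm, labels, _ = generate(FixtureSpec(seed=0))
cfg = FsqssaConfig(max_iter=30)

run = run_pipeline(cm, k=2, true_labels=labels, cfg=cfg, hvg=200, seed=100)
print(f"selected genes: {len(run.selected_genes)}")
print(f"best fitness:   {run.fitness:.4f}")
print("validity vs planted labels:")
for key in ("ri", "ari", "nmi", "ami", "acc", "fmi"):
    print(f"  {key:>4}: {run.metrics[key]:.4f}")

run_unk = run_pipeline(cm, k=None, true_labels=labels, cfg=cfg, hvg=200, seed=100)
print(f"with K unknown, Louvain estimated K = {run_unk.k_used} "
      f"(ARI {run_unk.metrics['ari']:.4f})")
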