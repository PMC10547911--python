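"""Preprocess a raw count matrix: gene filtering, normalization, HVG screen.

Builds a small synthetic count matrix, then applies the standard chain:
drop all-zero genes, scale each cell to the median library size, log2
transform, and keep the most variable genes.
"""

from scfse import FixtureSpec, generate, filter_zero_genes, normalize_log, select_hvg

cm, _, _ = generate(FixtureSpec(n_cells=100, n_genes=80, n_informative=10, seed=0))
print(f"raw counts:       {cm.n_cells} cells x {cm.n_genes} genes, "
      f"{(cm.values == 0).mean():.1%} zeros")

filtered = filter_zero_genes(cm)
print(f"after zero-gene filter: {filtered.n_genes} genes")

expr = normalize_log(filtered)
print(f"log2 expression range: [{expr.values.min():.2f}, {expr.values.max():.2f}]")

hvg = select_hvg(expr, 40)
print(f"top highly variable genes kept: {hvg.n_genes}")
# The HVG matrix is the search space for gene selection: each retained gene
# becomes one quantum bit in the squirrel-search optimizer.
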