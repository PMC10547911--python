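"""Synthetic scRNA-seq-like count matrices with planted cluster structure.

Cells are assigned round-robin to ``K_true`` clusters.  A chosen set of
informative genes receives cluster-specific negative-binomial means
``base_mean * 2^(effect * z)`` with balanced up/down offsets ``z = ±1/2``
per cluster, so the log-fold separation between cluster means equals
``effect``; the remaining noise genes share one mean across clusters.
Optional Bernoulli dropout zeroes a fraction of entries to emulate the
sparsity of real single-cell data; it defaults off because at desk scale
uniform dropout gives every noise gene a strong zero/non-zero bimodality
that dominates silhouette-based objectives (see the methods note).
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .io import CountMatrix, write_count_matrix

__all__ = ["FixtureSpec", "generate", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one planted-structure fixture."""

    n_cells: int = 200
    n_genes: int = 200
    K_true: int = 2
    n_informative: int = 20
    effect: float = 2.0          # log2 fold separation between cluster means
    base_mean: float = 5.0       # NB mean of a typical gene
    dispersion: float = 0.2      # NB overdispersion: var = mu + disp * mu^2
    dropout: float = 0.0         # Bernoulli zeroing probability (off by default)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.K_true > self.n_cells:
            raise ValueError("K_true exceeds n_cells")
        if self.n_cells // self.K_true < 2:
            raise ValueError("each cluster needs at least 2 cells")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.base_mean <= 0 or self.effect < 0 or self.dispersion < 0:
            raise ValueError("base_mean must be > 0; effect, dispersion >= 0")


def _nb_sample(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion < 1e-12:  # Poisson limit
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate(spec: FixtureSpec) -> tuple[CountMatrix, np.ndarray, list[str]]:
    """Draw one fixture: counts, true cluster labels, informative gene ids."""
    rng = np.random.default_rng(spec.seed)
    labels = np.arange(spec.n_cells) % spec.K_true
    gene_ids = [f"g{j:04d}" for j in range(spec.n_genes)]
    cell_ids = [f"c{i:04d}" for i in range(spec.n_cells)]
    informative = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )

    # Per-cluster mean for every gene: noise genes flat at base_mean,
    # informative genes split into balanced up/down clusters (z = ±1/2).
    mu = np.full((spec.K_true, spec.n_genes), spec.base_mean, dtype=float)
    half = spec.K_true // 2
    for j in informative:
        z = np.full(spec.K_true, 0.5)
        z[:max(half, 1)] = -0.5
        rng.shuffle(z)
        mu[:, j] = spec.base_mean * 2.0 ** (spec.effect * z)

    counts = _nb_sample(mu[labels, :], spec.dispersion, rng)
    if spec.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= spec.dropout)
    cm = CountMatrix(counts.astype(np.int64), cell_ids, gene_ids)
    informative_ids = [gene_ids[j] for j in informative]
    return cm, labels, informative_ids


def write_fixture(
    spec: FixtureSpec, out_dir: str | Path, format: str = "csv"
) -> dict[str, Path]:
    """Write counts (CSV or MTX triplet), labels.csv and informative_genes.txt."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cm, labels, informative_ids = generate(spec)
    if format == "csv":
        matrix_path = out_dir / "counts.csv"
    elif format == "mtx":
        matrix_path = out_dir / "counts.mtx"
    else:
        raise ValueError(f"unknown format {format!r}")
    write_count_matrix(cm, matrix_path, format=format)
    labels_path = out_dir / "labels.csv"
    with open(labels_path, "w") as fh:
        fh.write("cell_id,cluster\n")
        for cid, lab in zip(cm.cell_ids, labels):
            fh.write(f"{cid},{lab}\n")
    genes_path = out_dir / "informative_genes.txt"
    with open(genes_path, "w") as fh:
        fh.write("".join(f"{g}\n" for g in informative_ids))
    import json

    spec_path = out_dir / "fixture_spec.json"
    with open(spec_path, "w") as fh:
        json.dump(asdict(spec), fh, indent=2)
    return {
        "matrix": matrix_path,
        "labels": labels_path,
        "informative_genes": genes_path,
        "spec": spec_path,
    }
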