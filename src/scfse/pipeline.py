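"""End-to-end orchestration: preprocess → gene selection → cluster → evaluate.

``run_pipeline`` drives one full analysis of a count matrix: zero-gene
filtering, library-size normalization with log2 transform, top-D HVG
screening, FSQSSA gene selection, final clustering on the selected genes
(K-means when K is known, Louvain otherwise) and, when true labels are
available, the six-metric evaluation panel.  ``run_repeats`` replays the
pipeline across consecutive seeds and aggregates how often each gene is
selected, mirroring the repeated-run gene-frequency analysis.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .fitness import estimate_k_louvain, kmeans_cluster
from .fitness import fitness as score_mask
from .fsqssa import FsqssaConfig, FsqssaResult, TraceRecord, run_fsqssa
from .io import CountMatrix, ExpressionMatrix, filter_zero_genes, normalize_log, select_hvg
from .metrics import evaluate

__all__ = [
    "RunResult",
    "FrequencyTable",
    "select_genes",
    "run_pipeline",
    "run_repeats",
    "top_frequent_genes",
]

logger = logging.getLogger("scfse")


@dataclass
class RunResult:
    """Everything one pipeline run produced, sufficient to reproduce it."""

    selected_genes: list[str]
    labels: np.ndarray
    fitness: float
    metrics: dict | None
    trace: list[TraceRecord]
    config_echo: dict
    seed: int
    k_used: int
    k_estimated: int | None = None


@dataclass
class FrequencyTable:
    """Per-gene selection counts over repeated independent runs."""

    counts: dict[str, int]
    n_runs: int


def select_genes(
    expr: ExpressionMatrix,
    K: int,
    cfg: FsqssaConfig,
    rng: np.random.Generator,
    fitness_fn=None,
) -> FsqssaResult:
    """FSQSSA search over the genes of ``expr`` with the K-means fitness.

    A custom ``fitness_fn(mask) -> float`` may replace the default
    silhouette/parsimony objective (used by tests with analytic objectives).
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if expr.n_cells < K:
        raise ValueError("need at least K cells")
    if fitness_fn is None:

        def fitness_fn(mask):
            return score_mask(expr, mask, K, cfg.w, rng).value

    return run_fsqssa(expr.n_genes, cfg, fitness_fn, rng)


def run_pipeline(
    counts: CountMatrix,
    k: int | None = None,
    true_labels=None,
    cfg: FsqssaConfig | None = None,
    hvg: int = 2000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_neighbors: int = 15,
) -> RunResult:
    """One full analysis of a raw count matrix.

    When ``k`` is None the cluster count is estimated by Louvain — once on
    the full HVG matrix to give the in-search K-means a K, and again on the
    selected genes for the final labels.  Artifacts (mask, labels, trace,
    metrics, config echo) are written under ``out_dir`` when given.
    """
    cfg = cfg or FsqssaConfig()
    rng = np.random.default_rng(seed)

    filtered = filter_zero_genes(counts)
    logger.info("filtered zero genes: %d -> %d", counts.n_genes, filtered.n_genes)
    expr = normalize_log(filtered)
    expr = select_hvg(expr, hvg)
    logger.info("HVG screen retained D=%d genes", expr.n_genes)

    k_estimated = None
    if k is None:
        k_estimated, _ = estimate_k_louvain(
            expr, n_neighbors=n_neighbors, seed=seed
        )
        k_search = max(k_estimated, 2)
        logger.info("Louvain estimated K=%d on the HVG matrix", k_estimated)
    else:
        k_search = k

    result = select_genes(expr, k_search, cfg, rng)
    mask = result.mask.astype(bool)
    selected = [g for g, m in zip(expr.gene_ids, mask) if m]
    logger.info("selected %d / %d genes, fitness %.4f",
                len(selected), expr.n_genes, result.fitness)

    if k is None:
        k_final, labels = estimate_k_louvain(
            expr, mask, n_neighbors=n_neighbors, seed=seed
        )
        k_estimated = k_final
    else:
        k_final = k
        labels = kmeans_cluster(expr, mask, k, rng)

    metrics = None
    if true_labels is not None:
        metrics = evaluate(true_labels, labels)

    config_echo = {
        "cfg": asdict(cfg),
        "k": k,
        "hvg": hvg,
        "seed": seed,
        "n_neighbors": n_neighbors,
    }
    run = RunResult(
        selected_genes=selected,
        labels=np.asarray(labels),
        fitness=result.fitness,
        metrics=metrics,
        trace=result.trace,
        config_echo=config_echo,
        seed=seed,
        k_used=k_final,
        k_estimated=k_estimated,
    )
    if out_dir is not None:
        write_run(run, expr, out_dir)
    return run


def write_run(run: RunResult, expr: ExpressionMatrix, out_dir: str | Path) -> None:
    """Write the run artifacts as plain-text files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "selected_genes.txt", "w") as fh:
        fh.write("".join(f"{g}\n" for g in run.selected_genes))
    with open(out / "selected_genes.json", "w") as fh:
        json.dump(
            {
                "fitness": run.fitness,
                "n_selected": len(run.selected_genes),
                "seed": run.seed,
                "config": run.config_echo,
            },
            fh,
            indent=2,
        )
    with open(out / "labels.csv", "w") as fh:
        fh.write("cell_id,cluster\n")
        for cid, lab in zip(expr.cell_ids, run.labels):
            fh.write(f"{cid},{int(lab)}\n")
    with open(out / "trace.csv", "w") as fh:
        fh.write("iteration,best_fitness,mean_fitness,n_selected_best\n")
        for rec in run.trace:
            fh.write(
                f"{rec.iteration},{rec.best_fitness!r},"
                f"{rec.mean_fitness!r},{rec.n_selected_best}\n"
            )
    if run.metrics is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(run.metrics, fh, indent=2)
    with open(out / "config.json", "w") as fh:
        json.dump(run.config_echo, fh, indent=2)


def run_repeats(
    counts: CountMatrix,
    n_runs: int,
    base_seed: int = 0,
    k: int | None = None,
    true_labels=None,
    cfg: FsqssaConfig | None = None,
    hvg: int = 2000,
    out_dir: str | Path | None = None,
) -> tuple[FrequencyTable, list[RunResult]]:
    """Repeat the pipeline with seeds base_seed .. base_seed + n_runs − 1.

    Each run uses an independent seed-derived random stream, so results do
    not depend on execution order.  Failed runs are excluded with a warning;
    if every run fails the error is raised.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    results: list[RunResult] = []
    counts_by_gene: dict[str, int] = {}
    last_error: Exception | None = None
    for i in range(n_runs):
        seed = base_seed + i
        run_dir = Path(out_dir) / f"run_{seed:05d}" if out_dir else None
        try:
            run = run_pipeline(
                counts, k=k, true_labels=true_labels, cfg=cfg,
                hvg=hvg, seed=seed, out_dir=run_dir,
            )
        except Exception as exc:  # noqa: BLE001 - isolate individual run failures
            warnings.warn(f"run with seed {seed} failed: {exc!r}", RuntimeWarning,
                          stacklevel=2)
            last_error = exc
            continue
        results.append(run)
        for g in run.selected_genes:
            counts_by_gene[g] = counts_by_gene.get(g, 0) + 1
    if not results:
        raise RuntimeError(f"all {n_runs} runs failed") from last_error
    table = FrequencyTable(counts=counts_by_gene, n_runs=len(results))
    if out_dir is not None:
        with open(Path(out_dir) / "frequency.csv", "w") as fh:
            fh.write("gene_id,count\n")
            for g, c in sorted(table.counts.items(),
                               key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{g},{c}\n")
    return table, results


def top_frequent_genes(table: FrequencyTable, top_n: int = 50) -> list[str]:
    """Genes ranked by selection frequency (descending), ties lexicographic."""
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:top_n]]
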