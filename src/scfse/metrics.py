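"""External clustering-validity metrics: RI, ARI, NMI, AMI, ACC, FMI.

All metrics compare a ground-truth partition ``truth`` with a predicted
partition ``pred`` over the same cells and are invariant to relabeling of
either side.  The pair-counting family (RI, ARI, FMI, pairwise ACC) works
on the 2x2 table of unordered cell pairs; the information-theoretic family
(NMI, AMI) works on the contingency table.  ACC additionally has a
Hungarian mode that optimally matches predicted clusters to true classes
and reports the matched-cell fraction — the convention most single-cell
benchmarks mean by "clustering accuracy".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    fowlkes_mallows_score,
    normalized_mutual_info_score,
)
from sklearn.metrics.cluster import contingency_matrix

__all__ = [
    "PairCounts",
    "pair_counts",
    "rand_index",
    "adjusted_rand_index",
    "nmi",
    "ami",
    "clustering_accuracy",
    "fmi",
    "evaluate",
]


def _as_labels(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(truth).ravel()
    v = np.asarray(pred).ravel()
    if u.shape != v.shape:
        raise ValueError(f"label vectors differ in length: {u.size} vs {v.size}")
    if u.size < 2:
        raise ValueError("need at least 2 labeled cells")
    return u, v


@dataclass(frozen=True)
class PairCounts:
    """Unordered-pair agreement table between two partitions.

    TP: same cluster in both; TN: different in both; FP: same in prediction
    only; FN: same in truth only.  The four counts sum to C(n, 2).
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def pair_counts(truth, pred) -> PairCounts:
    """Count pairwise agreements via the contingency table (O(K_u * K_v))."""
    u, v = _as_labels(truth, pred)
    n = u.size
    cont = contingency_matrix(u, v)
    same_both = int((cont * (cont - 1) // 2).sum())
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    same_u = int((a * (a - 1) // 2).sum())
    same_v = int((b * (b - 1) // 2).sum())
    total = n * (n - 1) // 2
    tp = same_both
    fn = same_u - tp
    fp = same_v - tp
    tn = total - tp - fn - fp
    return PairCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def rand_index(truth, pred) -> float:
    """Fraction of cell pairs on which the two partitions agree."""
    pc = pair_counts(truth, pred)
    return (pc.tp + pc.tn) / pc.total


def adjusted_rand_index(truth, pred) -> float:
    """Rand index corrected for chance agreement (1 iff identical partitions)."""
    u, v = _as_labels(truth, pred)
    return float(adjusted_rand_score(u, v))


def nmi(truth, pred) -> float:
    """Mutual information normalized by the mean of the two entropies."""
    u, v = _as_labels(truth, pred)
    return float(normalized_mutual_info_score(u, v, average_method="arithmetic"))


def ami(truth, pred) -> float:
    """Mutual information adjusted for chance under the permutation model."""
    u, v = _as_labels(truth, pred)
    return float(adjusted_mutual_info_score(u, v, average_method="arithmetic"))


def clustering_accuracy(truth, pred, mode: str = "hungarian") -> float:
    """Clustering accuracy.

    ``hungarian`` (default): fraction of cells correctly assigned under the
    optimal one-to-one matching of predicted clusters to true classes.
    ``pairwise``: (TP + TN) / C(n, 2) over cell pairs, which is
    algebraically identical to the Rand index; provided because pair-based
    accuracy definitions occur in the literature.
    """
    u, v = _as_labels(truth, pred)
    if mode == "pairwise":
        return rand_index(u, v)
    if mode != "hungarian":
        raise ValueError(f"unknown accuracy mode {mode!r}")
    cont = contingency_matrix(u, v)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / u.size)


def fmi(truth, pred) -> float:
    """Fowlkes–Mallows index: geometric mean of pairwise precision and recall."""
    u, v = _as_labels(truth, pred)
    return float(fowlkes_mallows_score(u, v))


def evaluate(truth, pred) -> dict:
    """All six metrics plus basic partition facts, as a JSON-ready dict."""
    u, v = _as_labels(truth, pred)
    return {
        "ri": rand_index(u, v),
        "ari": adjusted_rand_index(u, v),
        "nmi": nmi(u, v),
        "ami": ami(u, v),
        "acc": clustering_accuracy(u, v),
        "fmi": fmi(u, v),
        "n": int(u.size),
        "K_true": int(len(np.unique(u))),
        "K_pred": int(len(np.unique(v))),
    }
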