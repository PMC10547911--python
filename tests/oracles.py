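"""Independent brute-force reference implementations used only by tests.

Everything here works by direct enumeration (all unordered pairs, all
cluster matchings, exact binomial-coefficient arithmetic) so it shares no
code path with the package implementations it checks.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np


def pair_counts(u, v) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) by enumerating every unordered pair of cells."""
    tp = tn = fp = fn = 0
    for i, j in combinations(range(len(u)), 2):
        same_u = u[i] == u[j]
        same_v = v[i] == v[j]
        if same_u and same_v:
            tp += 1
        elif not same_u and not same_v:
            tn += 1
        elif same_v:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def rand_index(u, v) -> float:
    tp, tn, fp, fn = pair_counts(u, v)
    return (tp + tn) / (tp + tn + fp + fn)


def fmi(u, v) -> float:
    tp, tn, fp, fn = pair_counts(u, v)
    denom = math.sqrt((tp + fp) * (tp + fn))
    return tp / denom if denom > 0 else 0.0


def contingency(u, v) -> np.ndarray:
    us, vs = sorted(set(u)), sorted(set(v))
    return np.array(
        [[sum(1 for x, y in zip(u, v) if x == a and y == b) for b in vs] for a in us]
    )


def adjusted_rand_index(u, v) -> float:
    cont = contingency(u, v)
    n = len(u)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    sum_ij = sum(math.comb(int(x), 2) for x in cont.ravel())
    sum_a = sum(math.comb(int(x), 2) for x in a)
    sum_b = sum(math.comb(int(x), 2) for x in b)
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(u, v) -> float:
    cont = contingency(u, v)
    n = len(u)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    mi = 0.0
    for i in range(cont.shape[0]):
        for j in range(cont.shape[1]):
            nij = cont[i, j]
            if nij:
                mi += nij / n * math.log(n * nij / (a[i] * b[j]))
    return mi


def nmi(u, v) -> float:
    cont = contingency(u, v)
    n = len(u)
    hu = _entropy(cont.sum(axis=1), n)
    hv = _entropy(cont.sum(axis=0), n)
    if hu + hv == 0:
        return 1.0
    return mutual_information(u, v) / ((hu + hv) / 2)


def expected_mutual_information(u, v) -> float:
    """E[MI] under the permutation (hypergeometric) model, exact arithmetic."""
    cont = contingency(u, v)
    n = len(u)
    a = cont.sum(axis=1)
    b = cont.sum(axis=0)
    emi = 0.0
    for ai in (int(x) for x in a):
        for bj in (int(x) for x in b):
            for nij in range(max(1, ai + bj - n), min(ai, bj) + 1):
                prob = (
                    math.comb(bj, nij)
                    * math.comb(n - bj, ai - nij)
                    / math.comb(n, ai)
                )
                emi += prob * nij / n * math.log(n * nij / (ai * bj))
    return emi


def ami(u, v) -> float:
    cont = contingency(u, v)
    n = len(u)
    hu = _entropy(cont.sum(axis=1), n)
    hv = _entropy(cont.sum(axis=0), n)
    if hu == 0 and hv == 0:
        return 1.0
    emi = expected_mutual_information(u, v)
    denom = (hu + hv) / 2 - emi
    if denom == 0:
        return 1.0
    return (mutual_information(u, v) - emi) / denom


def hungarian_accuracy(u, v) -> float:
    """Matched-cell fraction maximized over all cluster-to-class matchings."""
    cont = contingency(u, v)
    k = max(cont.shape)
    padded = np.zeros((k, k), dtype=int)
    padded[: cont.shape[0], : cont.shape[1]] = cont
    best = max(sum(padded[i, p[i]] for i in range(k)) for p in permutations(range(k)))
    return best / len(u)


def silhouette(x: np.ndarray, labels) -> float:
    """Mean silhouette by direct per-point distance averaging."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():  # singleton cluster
            scores.append(0.0)
            continue
        a = dist[i, own].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in set(labels) - {labels[i]}
        )
        scores.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(scores))
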