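"""Independent brute-force oracles used to check the fast implementations.

These deliberately re-derive each quantity by the most literal route —
full O(p) random walks, pairwise agglomeration over explicit cluster sets,
per-pair confusion counting — and share no code with the package paths
they validate.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_walk(rank: np.ndarray, set_idx, tau: float, mode: str) -> float:
    """Step-by-step enrichment walk for one sample.

    ``rank`` is the 1-based rank of each gene (rank 1 = first visited);
    ``set_idx`` the indices of the set genes.
    """
    p = len(rank)
    set_idx = set(int(i) for i in set_idx)
    k = len(set_idx)
    order = np.argsort(rank)  # gene visited at each position
    weights = {i: abs(p / 2.0 - rank[i]) ** tau for i in set_idx}
    denom = sum(weights.values())
    if denom == 0:
        weights = {i: 1.0 for i in set_idx}
        denom = float(k)
    running = 0.0
    max_dev = 0.0
    min_dev = 0.0
    for gene in order:
        if gene in set_idx:
            running += weights[gene] / denom
        else:
            running -= 1.0 / (p - k)
        max_dev = max(max_dev, running)
        min_dev = min(min_dev, running)
    if mode == "max_diff":
        return max_dev + min_dev
    # positive deviation wins magnitude near-ties (same rule as the package)
    return max_dev if max_dev >= -min_dev - 1e-12 else min_dev


def brute_force_kernel_z(X: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Double-loop Gaussian-kernel CDF statistic."""
    from scipy.stats import norm

    p, n = X.shape
    z = np.zeros_like(X, dtype=float)
    for i in range(p):
        h = max(np.std(X[i], ddof=1) / 4.0, floor)
        for j in range(n):
            z[i, j] = np.mean([norm.cdf((X[i, j] - X[i, k]) / h) for k in range(n)])
    return z


def brute_force_complete_linkage(D: np.ndarray) -> list[list[frozenset]]:
    """Agglomerate with complete linkage; returns the partition at each step.

    ``D`` is a full symmetric distance matrix over the items.  Output item k
    is the partition with (n - k) clusters; ties merge the lexicographically
    smallest cluster pair.
    """
    n = D.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    partitions = [list(clusters)]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            key = (d, sorted(clusters[a])[0], sorted(clusters[b])[0])
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [merged]
        partitions.append(list(clusters))
    return partitions


def brute_force_confusion(pred, truth) -> tuple[int, int, int, int]:
    """Per-pair confusion tally: (tp, fp, tn, fn)."""
    tp = fp = tn = fn = 0
    for p_, t_ in zip(pred, truth):
        if p_ and t_:
            tp += 1
        elif p_ and not t_:
            fp += 1
        elif not p_ and not t_:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def partition_key(groups) -> frozenset:
    """Canonical form of a partition for order-insensitive comparison."""
    return frozenset(frozenset(g) for g in groups)


def labels_to_partition(labels, items=None) -> frozenset:
    labels = list(labels)
    items = list(items) if items is not None else list(range(len(labels)))
    groups: dict = {}
    for item, lab in zip(items, labels):
        groups.setdefault(lab, set()).add(item)
    return partition_key(groups.values())
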