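"""Single-sample gene-set enrichment and a permutation over-representation test.

The per-sample score follows the GSVA construction:

1. For each gene i, a Gaussian-kernel CDF estimate across samples,
   ``z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i)`` with bandwidth
   ``h_i = s_i / 4`` (sample standard deviation, floored at a small eps).
2. Within each sample, genes are ordered by decreasing z (ties broken by
   lexicographic gene symbol) and assigned the centered rank statistic
   ``r_ij = |p/2 - rank_ij|`` (rank 1 = largest z).
3. A Kolmogorov-Smirnov-like random walk over that ordering steps up by
   ``|r|^tau / sum_set |r|^tau`` at set genes and down by ``1/(p - k)``
   otherwise.  The score is the sum of the maximum positive and minimum
   negative deviation (``max_diff``), or the single deviation of largest
   magnitude (``max_dev``).

The walk is evaluated only at hit positions, O(k) per sample after
preprocessing, which makes scoring 10^5 random same-size sets per sample
feasible.  The permutation test compares the observed score E of the study
set against scores F of sets drawn uniformly from the gene universe; the
default p-value is the smoothed ``(1 + #{F >= E}) / (1 + I)``, with the
unsmoothed ratio ``#{E > F} / I`` available as ``verbatim`` mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from pdxnet.io import ExpressionMatrix

BANDWIDTH_FLOOR = 1e-8


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols."""

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members) -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", tuple(dict.fromkeys(members)))
        if len(self.members) < 1:
            raise ValueError("gene set must have at least one member")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class RankStatistics:
    """Kernel-CDF scores and per-sample gene orderings.

    ``rank`` is 1-based: rank 1 is the gene with the largest kernel-CDF
    statistic in that sample.  Within a sample the ranks are a permutation
    of 1..p.
    """

    z: np.ndarray            # p x n kernel CDF statistic
    rank: np.ndarray         # p x n int, 1-based rank by decreasing z
    gene_ids: list[str]
    sample_ids: list[str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def member_indices(self, gene_set: GeneSet) -> np.ndarray:
        missing = [g for g in gene_set.members if g not in self._index]
        if missing:
            raise ValueError(f"gene set members absent from universe: {missing}")
        return np.array([self._index[g] for g in gene_set.members])


@dataclass(frozen=True)
class PermutationResult:
    sample_id: str
    observed_score: float
    iterations: int
    exceed_count: int        # #{F >= E}
    p_value: float
    mode: str                # "smoothed" | "verbatim"


def kernel_cdf_statistic(
    expr: ExpressionMatrix, bandwidth_floor: float = BANDWIDTH_FLOOR
) -> RankStatistics:
    """Gaussian-kernel CDF scores and decreasing-z rank orderings per sample."""
    if expr.scale != "log2_normalized":
        raise ValueError("kernel statistic expects log2-normalized expression")
    X = expr.data.to_numpy(dtype=float)
    p, n = X.shape
    if n < 3:
        raise ValueError("kernel density estimation needs at least 3 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression values must be finite")

    h = np.maximum(X.std(axis=1, ddof=1) / 4.0, bandwidth_floor)
    z = np.empty_like(X)
    # chunk genes to bound the p x n x n pairwise-difference workspace
    chunk = max(1, int(2e7 // (n * n)))
    for start in range(0, p, chunk):
        sl = slice(start, start + chunk)
        diffs = (X[sl, :, None] - X[sl, None, :]) / h[sl, None, None]
        z[sl] = ndtr(diffs).mean(axis=2)

    # ties in z broken by lexicographic gene symbol, for reproducibility
    gene_ids = expr.gene_ids
    lexpos = np.argsort(np.argsort(np.asarray(gene_ids)))
    rank = np.empty((p, n), dtype=np.int64)
    positions = np.arange(1, p + 1)
    for j in range(n):
        order = np.lexsort((lexpos, -z[:, j]))
        rank[order, j] = positions
    return RankStatistics(z=z, rank=rank, gene_ids=list(gene_ids), sample_ids=expr.sample_ids)


def _walk_extrema(
    pos: np.ndarray, p: int, tau: float, mode: str
) -> np.ndarray:
    """Enrichment scores from sorted 0-based hit positions.

    ``pos`` has shape (..., k, n): per instance and sample, the positions of
    the k set genes in the decreasing-z ordering, sorted ascending along the
    hit axis.  Only hit positions are visited: between hits the walk
    decreases linearly, so its extrema occur immediately before/after hits
    (and at the walk's endpoints, where it equals 0).
    """
    k = pos.shape[-2]
    if k >= p:
        raise ValueError("gene set must be smaller than the gene universe")
    rank = pos + 1
    w = np.abs(p / 2.0 - rank) ** tau
    tot = w.sum(axis=-2, keepdims=True)
    # degenerate all-zero weights (possible at tau>0 when every hit sits at
    # rank p/2): fall back to uniform steps
    w = np.where(tot == 0, 1.0, w)
    tot = w.sum(axis=-2, keepdims=True)
    cum = np.cumsum(w, axis=-2) / tot

    j = np.arange(k).reshape((k, 1))
    misses = (pos - j) / (p - k)           # misses walked before each hit
    after = cum - misses                   # walk value just after each hit
    before = after - w / tot               # walk value just before each hit

    max_pos = np.maximum(after.max(axis=-2), 0.0)
    min_neg = np.minimum(before.min(axis=-2), 0.0)
    if mode == "max_diff":
        return max_pos + min_neg
    if mode == "max_dev":
        # near-ties in magnitude resolve to the positive deviation so that
        # different summation orders cannot flip the sign
        return np.where(max_pos >= -min_neg - 1e-12, max_pos, min_neg)
    raise ValueError(f"unknown score mode: {mode!r}")


def enrichment_score(
    ranks: RankStatistics,
    gene_set: GeneSet,
    tau: float = 1.0,
    mode: str = "max_diff",
) -> pd.Series:
    """Per-sample enrichment score E of ``gene_set`` (O(k) per sample)."""
    idx = ranks.member_indices(gene_set)
    pos = np.sort(ranks.rank[idx, :] - 1, axis=0)
    scores = _walk_extrema(pos, ranks.n_genes, tau, mode)
    return pd.Series(scores, index=ranks.sample_ids, name=gene_set.name)


def scale_scores(scores: pd.Series) -> pd.Series:
    """Divide by the cohort's maximum absolute score; output in [-1, 1]."""
    if len(scores) < 1:
        raise ValueError("need at least one score")
    m = float(np.max(np.abs(scores.to_numpy())))
    if m == 0:
        warnings.warn("all enrichment scores are zero; returning unscaled")
        return scores.copy()
    return scores / m


def sample_random_set(
    universe, k: int, rng: np.random.Generator, exclude=None, name: str = "random"
) -> GeneSet:
    """k distinct symbols drawn uniformly without replacement from the universe."""
    pool = [g for g in universe if g not in set(exclude)] if exclude else list(universe)
    if k >= len(pool):
        raise ValueError("set size must be smaller than the (remaining) universe")
    return GeneSet(name, rng.choice(np.asarray(pool, dtype=object), size=k, replace=False))


def permutation_test(
    expr: ExpressionMatrix | RankStatistics,
    gene_set: GeneSet,
    iterations: int = 100_000,
    mode: str = "smoothed",
    seed: int | None = None,
    tau: float = 1.0,
    score_mode: str = "max_diff",
    exclude_set: bool = False,
    batch_size: int = 256,
) -> list[PermutationResult]:
    """Permutation over-representation test of a gene set, per sample.

    Rank statistics are computed once; in each of ``iterations`` draws a
    random set of the same size is scored in every sample.  ``exceed_count``
    is #{F >= E}; the smoothed p-value is (1 + exceed) / (1 + iterations),
    the verbatim one #{E > F} / iterations (complementary count).  With
    ``exclude_set`` the random sets avoid the observed set's members.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if mode not in ("smoothed", "verbatim"):
        raise ValueError(f"unknown p-value mode: {mode!r}")
    ranks = expr if isinstance(expr, RankStatistics) else kernel_cdf_statistic(expr)

    observed = enrichment_score(ranks, gene_set, tau=tau, mode=score_mode)
    E = observed.to_numpy()
    p, k = ranks.n_genes, len(gene_set)

    set_idx = ranks.member_indices(gene_set)
    pool = np.setdiff1d(np.arange(p), set_idx) if exclude_set else np.arange(p)
    if k >= len(pool):
        raise ValueError("gene set as large as the sampling pool")

    rng = np.random.default_rng(seed)
    exceed = np.zeros(ranks.n_samples, dtype=np.int64)
    done = 0
    while done < iterations:
        b = min(batch_size, iterations - done)
        keys = rng.random((b, len(pool)))
        draw = pool[np.argpartition(keys, k, axis=1)[:, :k]]
        pos = np.sort(ranks.rank[draw, :] - 1, axis=1)       # (b, k, n)
        F = _walk_extrema(pos, p, tau, score_mode)           # (b, n)
        exceed += (F >= E[None, :]).sum(axis=0)
        done += b

    results = []
    for sid, e, m in zip(ranks.sample_ids, E, exceed):
        if mode == "smoothed":
            pval = (1 + int(m)) / (1 + iterations)
        else:
            pval = (iterations - int(m)) / iterations
        results.append(
            PermutationResult(sid, float(e), iterations, int(m), pval, mode)
        )
    return results


def permutation_frame(results: list[PermutationResult]) -> pd.DataFrame:
    """Tabulate permutation results with cohort-scaled scores."""
    frame = pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "E": [r.observed_score for r in results],
            "exceed_count": [r.exceed_count for r in results],
            "p_value": [r.p_value for r in results],
        }
    ).set_index("sample")
    frame.insert(1, "scaled_E", scale_scores(frame["E"]))
    return frame
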