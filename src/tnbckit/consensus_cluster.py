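"""Monti-style consensus k-means with CDF-based selection of cluster number.

Subtype discovery proceeds in three steps:

1. ``select_features`` keeps the most variable genes (top fraction of
   per-gene standard deviations); when two cohorts are clustered
   independently, ``union_features`` combines their selections so both use
   the same feature space.
2. ``consensus_kmeans`` repeatedly subsamples the cohort (80% of samples by
   default), runs k-means on each subsample, and records for every sample
   pair the fraction of co-sampled runs in which the pair co-clustered —
   the consensus matrix M_k.  Final labels at each k cut an average-linkage
   tree built on 1 - M_k.
3. ``consensus_cdf_areas`` summarizes each M_k by the area A(k) under the
   empirical CDF of its entries, and ``choose_k`` applies the
   relative-area-change elbow rule Δ(k) to pick the number of clusters.

A crisp consensus matrix (entries near 0/1) has a flat CDF in the interior
and hence a large area; A(k) stops growing once k exceeds the true number
of clusters, which is what the Δ(k) >= threshold rule detects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from threadpoolctl import threadpool_limits

from .expr_data import ExpressionMatrix

logger = logging.getLogger(__name__)


def select_features(m: ExpressionMatrix, top_fraction: float = 0.10) -> list[str]:
    """Genes ranked by per-gene sample SD, keeping ceil(top_fraction * G).

    Ties in SD break lexicographically by gene id so reruns are stable.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples to rank genes by SD")
    sd = m.values.std(axis=1, ddof=1)
    n_keep = math.ceil(top_fraction * m.n_genes)
    order = sorted(zip(-sd.to_numpy(), m.gene_ids.astype(str)))
    return [g for _, g in order[:n_keep]]


def union_features(a: list[str], b: list[str]) -> list[str]:
    """Union of two gene lists preserving first-appearance order (a then b)."""
    seen: set[str] = set()
    out: list[str] = []
    for g in list(a) + list(b):
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


@dataclass
class ConsensusRun:
    """Results of a consensus run over a range of k."""

    k_range: list[int]
    n_iter: int
    subsample_fraction: float
    seed: int
    sample_ids: list[str]
    consensus: dict[int, np.ndarray] = field(default_factory=dict)
    cosample_counts: dict[int, np.ndarray] = field(default_factory=dict)
    labels: dict[int, np.ndarray] = field(default_factory=dict)
    A: dict[int, float] = field(default_factory=dict)
    delta: dict[int, float] = field(default_factory=dict)
    chosen_k: int | None = None

    def labels_series(self, k: int | None = None) -> pd.Series:
        k = self.chosen_k if k is None else k
        return pd.Series(self.labels[k], index=self.sample_ids, name=f"k{k}")

    def cdf_grid(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Empirical CDF of the consensus indices at k, for plotting.

        Returns (x, CDF(x)) over the sorted distinct upper-triangular
        entries augmented with 0 and 1.
        """
        M = self.consensus[k]
        vals = np.sort(M[np.triu_indices_from(M, k=1)])
        xs = np.unique(np.concatenate([[0.0], vals, [1.0]]))
        cdf = np.searchsorted(vals, xs, side="right") / vals.size
        return xs, cdf


def consensus_kmeans(
    m: ExpressionMatrix,
    k: int,
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
    max_lloyd_iter: int = 300,
    max_redraw_fraction: float = 0.1,
    return_counts: bool = False,
):
    """One consensus k-means run at a fixed k.

    Each iteration draws ``floor(f * n)`` samples without replacement (all
    genes kept), fits k-means (k-means++ init, Euclidean distance, samples
    as points) on the subsample, and accumulates co-clustering counts.
    M_k(i, j) = co-clustered / co-sampled, with diagonal 1; pairs never
    co-sampled (only possible at very small n_iter) are reported as 0.
    Final labels cut the average-linkage tree on 1 - M_k into k groups
    (integers 1..k).

    Per-iteration RNG streams are spawned deterministically from ``seed``,
    so identical seeds give bit-identical consensus matrices.  A subsample
    with fewer than k distinct points is re-drawn (logged); more than
    ``max_redraw_fraction`` of iterations re-drawn raises an error.
    """
    n = m.n_samples
    if k < 2:
        raise ValueError("k must be >= 2")
    m_sub = int(np.floor(subsample_fraction * n))
    if m_sub < k:
        raise ValueError(f"subsample size {m_sub} < k={k}")
    X = np.ascontiguousarray(m.values.to_numpy().T)  # samples x genes

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)

    cocluster = np.zeros((n, n), dtype=np.int32)
    cosample = np.zeros((n, n), dtype=np.int32)
    n_redraw = 0
    max_redraws = int(max_redraw_fraction * n_iter)

    with threadpool_limits(limits=1):  # many small fits; avoid thread thrash
        for child in children:
            rng = np.random.default_rng(child)
            while True:
                idx = rng.choice(n, m_sub, replace=False)
                sub = X[idx]
                if np.unique(sub, axis=0).shape[0] >= k:
                    break
                n_redraw += 1
                logger.info("subsample had < %d distinct points; re-drawing", k)
                if n_redraw > max_redraws:
                    raise RuntimeError(
                        f"more than {max_redraw_fraction:.0%} of iterations re-drawn; "
                        "data has too few distinct points for this k"
                    )
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=1,
                max_iter=max_lloyd_iter,
                random_state=int(rng.integers(2**31)),
            ).fit(sub)
            lab = km.labels_
            block = np.ix_(idx, idx)
            cosample[block] += 1
            cocluster[block] += lab[:, None] == lab[None, :]

    with np.errstate(invalid="ignore"):
        M = np.where(cosample > 0, cocluster / np.maximum(cosample, 1), 0.0)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0  # exact symmetry against float asymmetries

    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if return_counts:
        return M, labels, cosample
    return M, labels


def cdf_area(M: np.ndarray) -> float:
    """Area under the empirical CDF of the upper-triangular entries of M.

    The empirical CDF of consensus indices is a step function on [0, 1];
    its integral equals the left Riemann sum over the sorted distinct entry
    values augmented with 0 and 1 (equivalently 1 - mean of the entries).
    """
    vals = M[np.triu_indices_from(M, k=1)]
    xs = np.unique(np.concatenate([[0.0], np.sort(vals), [1.0]]))
    cdf = np.searchsorted(np.sort(vals), xs, side="right") / vals.size
    return float(np.sum(np.diff(xs) * cdf[:-1]))


def consensus_cdf_areas(
    consensus: dict[int, np.ndarray]
) -> tuple[dict[int, float], dict[int, float]]:
    """A(k) per k plus the relative area change Δ(k).

    Δ(2) = A(2) by convention; for k > 2, Δ(k) = (A(k) - A(k-1)) / A(k-1).
    """
    ks = sorted(consensus)
    A = {k: cdf_area(consensus[k]) for k in ks}
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = A[k]
        else:
            prev = A[ks[i - 1]]
            delta[k] = (A[k] - prev) / prev if prev > 0 else math.inf
    return A, delta


def choose_k(delta: dict[int, float], threshold: float = 0.05) -> int:
    """Largest k whose relative area change still meets the threshold.

    Returns the largest k with Δ(k) >= threshold; if no k >= 3 qualifies the
    minimum of the range is returned (no evidence of further structure).  A
    warning is logged when the boundary of the range is chosen, since the
    true k may lie beyond it.
    """
    ks = sorted(delta)
    qualifying = [k for k in ks if delta[k] >= threshold]
    if not qualifying or max(qualifying) < 3:
        return ks[0]
    chosen = max(qualifying)
    if chosen == ks[-1]:
        logger.warning("Δ(k) >= %.3g at the top of k_range; true k may exceed %d", threshold, chosen)
    return chosen


def run_consensus(
    m: ExpressionMatrix,
    k_range: range | list[int] = range(2, 11),
    n_iter: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    threshold: float = 0.05,
    force_k: int | None = None,
) -> ConsensusRun:
    """Consensus k-means over a range of k with automatic k selection."""
    ks = list(k_range)
    run = ConsensusRun(
        k_range=ks,
        n_iter=n_iter,
        subsample_fraction=subsample_fraction,
        seed=seed if isinstance(seed, int) else -1,
        sample_ids=list(m.sample_ids.astype(str)),
    )
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for k, child in zip(ks, master.spawn(len(ks))):
        M, labels, counts = consensus_kmeans(
            m,
            k,
            n_iter=n_iter,
            subsample_fraction=subsample_fraction,
            seed=child,
            return_counts=True,
        )
        run.consensus[k] = M
        run.labels[k] = labels
        run.cosample_counts[k] = counts
    run.A, run.delta = consensus_cdf_areas(run.consensus)
    run.chosen_k = force_k if force_k is not None else choose_k(run.delta, threshold)
    return run
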