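"""Consensus fuzzy c-means clustering of 4-point expression trajectories.

Between T = 4 sampled time points a trajectory can rise, fall or stay flat
at each of the three steps, giving 3^(T-1) = 27 possible sign paths; the
default cluster count k = 27 follows from that enumeration. Fuzzy c-means
(soft k-means with fuzzifier m > 1) is run many times from random starts;
per-run cluster labels are aligned by optimal centroid matching and the
consensus label of a gene is its modal aligned hard assignment. Cluster
centroids are then classified into four expression modes:

* EARLY — single peak at the first time point (decreasing trajectory),
* INTERMEDIATE — single interior peak,
* LATE — single peak at the last time point (increasing trajectory),
* BI_MODAL — two peaks,
* UNCLASSIFIED — flat (or expression below a detection floor).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .containers import (
    BI_MODAL,
    EARLY,
    INTERMEDIATE,
    LATE,
    UNCLASSIFIED,
    EchinodevError,
    ModeMap,
    TimeCourseMatrix,
)

__all__ = [
    "FuzzyResult",
    "ConsensusResult",
    "enumerate_paths",
    "fuzzy_cmeans",
    "consensus_assignment",
    "classify_centroid_mode",
    "assign_modes",
    "cluster_trajectories",
]


def enumerate_paths(T: int) -> tuple[int, list[tuple[str, ...]]]:
    """All sign paths a T-point trajectory can take between steps.

    Each of the T-1 steps is '+' (increase), '-' (decrease) or '0'
    (no change); returns ``(3**(T-1), patterns)``.
    """
    if T < 2:
        raise EchinodevError(f"need at least 2 time points, got {T}")
    patterns = [tuple(p) for p in itertools.product("+-0", repeat=T - 1)]
    return len(patterns), patterns


@dataclass
class FuzzyResult:
    """State of one fuzzy c-means run."""

    k: int
    m: float
    centroids: np.ndarray  # k x T
    membership: np.ndarray  # n x k, rows sum to 1
    objective: float
    objective_history: list[float]
    seed: int
    converged: bool

    def hard_labels(self) -> np.ndarray:
        return self.membership.argmax(axis=1)


def fuzzy_cmeans(
    X: np.ndarray,
    k: int = 27,
    m: float = 1.25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> FuzzyResult:
    """Standard fuzzy c-means with Euclidean distance.

    Alternates membership updates u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1))
    and weighted centroid updates c_j = sum_i u_ij^m x_i / sum_i u_ij^m,
    minimizing the objective sum_ij u_ij^m d_ij^2. A point coinciding with
    a centroid receives membership 1 for it. Initial centroids are k points
    sampled without replacement.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise EchinodevError("X must be a 2-D array")
    n, T = X.shape
    if not np.isfinite(X).all():
        raise EchinodevError("non-finite values in clustering input")
    if n < k:
        raise EchinodevError(f"need at least k={k} rows, got {n}")
    if m <= 1:
        raise EchinodevError("fuzzifier m must exceed 1")

    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    exponent = 2.0 / (m - 1.0)
    history: list[float] = []
    converged = False
    membership = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        d2 = cdist(X, centroids, "sqeuclidean")
        membership = _membership_from_distances(d2, exponent)
        um = membership**m
        denom = um.sum(axis=0)
        # a cluster that lost all weight keeps its previous centroid
        keep = denom > 0
        new_centroids = centroids.copy()
        new_centroids[keep] = (um.T[keep] @ X) / denom[keep, None]
        centroids = new_centroids
        d2 = cdist(X, centroids, "sqeuclidean")
        membership = _membership_from_distances(d2, exponent)
        obj = float((membership**m * d2).sum())
        history.append(obj)
        if len(history) >= 2 and abs(history[-2] - history[-1]) <= tol * max(history[-2], 1e-300):
            converged = True
            break
    return FuzzyResult(
        k=k,
        m=m,
        centroids=centroids,
        membership=membership,
        objective=history[-1],
        objective_history=history,
        seed=seed,
        converged=converged,
    )


def _membership_from_distances(d2: np.ndarray, exponent: float) -> np.ndarray:
    """Membership update; exact centroid hits get crisp membership."""
    n, k = d2.shape
    u = np.empty_like(d2)
    zero_rows = (d2 == 0).any(axis=1)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = d2 ** (-exponent / 2.0)  # d^(-2/(m-1)) with d2 = d^2
        np.divide(inv, inv.sum(axis=1, keepdims=True), out=u)
    if zero_rows.any():
        u[zero_rows] = 0.0
        idx = np.flatnonzero(zero_rows)
        hit = d2[idx].argmin(axis=1)
        u[idx, hit] = 1.0
    return u


@dataclass
class ConsensusResult:
    """Modal aligned hard assignment over repeated fuzzy runs."""

    runs: int
    hard_labels_per_run: np.ndarray  # n x runs, aligned to run 0
    consensus_label: np.ndarray  # n
    consensus_support: np.ndarray  # n, modal fraction in (0, 1]
    consensus_centroids: np.ndarray  # k x T, mean of aligned centroids


def consensus_assignment(run_results: list[FuzzyResult]) -> ConsensusResult:
    """Align per-run cluster labels and take the modal label per gene.

    Labels of every run are matched to run 0 by minimum-total Euclidean
    centroid distance (Hungarian assignment). The consensus label is the
    most frequent aligned hard label; ties break by highest mean membership
    for the tied cluster, then lowest cluster index.
    """
    if len(run_results) < 2:
        raise EchinodevError("consensus needs at least 2 runs")
    k = run_results[0].k
    T = run_results[0].centroids.shape[1]
    for r in run_results:
        if r.k != k or r.centroids.shape[1] != T:
            raise EchinodevError("runs disagree on k or trajectory length")

    n = run_results[0].membership.shape[0]
    runs = len(run_results)
    aligned_labels = np.empty((n, runs), dtype=np.int64)
    aligned_membership_sum = np.zeros((n, k))
    aligned_centroids = np.zeros((k, T))
    ref = run_results[0].centroids
    for r, res in enumerate(run_results):
        cost = cdist(ref, res.centroids)
        row, col = linear_sum_assignment(cost)  # row is 0..k-1 for a square cost
        # perm[j] = aligned index of run-r cluster j
        perm = np.empty(k, dtype=np.int64)
        perm[col] = row
        aligned_labels[:, r] = perm[res.hard_labels()]
        aligned_membership_sum += res.membership[:, col]
        aligned_centroids += res.centroids[col]
    aligned_centroids /= runs

    votes = np.zeros((n, k), dtype=np.int64)
    for r in range(runs):
        votes[np.arange(n), aligned_labels[:, r]] += 1
    top = votes.max(axis=1)
    consensus = np.empty(n, dtype=np.int64)
    mean_membership = aligned_membership_sum / runs
    for i in range(n):
        tied = np.flatnonzero(votes[i] == top[i])
        if len(tied) == 1:
            consensus[i] = tied[0]
        else:  # break by mean membership, then lowest index
            best = tied[np.argmax(mean_membership[i, tied])]
            consensus[i] = best
    support = top / runs
    return ConsensusResult(
        runs=runs,
        hard_labels_per_run=aligned_labels,
        consensus_label=consensus,
        consensus_support=support,
        consensus_centroids=aligned_centroids,
    )


def classify_centroid_mode(c: np.ndarray, flat_eps: float = 0.05) -> str:
    """Classify a 4-point trajectory by its peak structure.

    Step differences with magnitude at most ``flat_eps * max(c)`` count as
    flat. Peaks are local maxima of the sign pattern with endpoints
    included: the trajectory peaks at the start if its first non-flat step
    falls, at the end if its last non-flat step rises, and at an interior
    point wherever a rise is later followed by a fall.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or len(c) != 4:
        raise EchinodevError(f"expected a 4-point trajectory, got shape {c.shape}")
    if (c < 0).any():
        raise EchinodevError("negative trajectory values")
    eps = flat_eps * c.max()
    d = np.diff(c)
    signs = np.where(np.abs(d) <= eps, 0, np.sign(d)).astype(int)
    nz = signs[signs != 0]
    if len(nz) == 0:
        return UNCLASSIFIED
    start_peak = nz[0] == -1
    end_peak = nz[-1] == 1
    interior_peaks = int(((nz[:-1] == 1) & (nz[1:] == -1)).sum())
    total = int(start_peak) + int(end_peak) + interior_peaks
    if total >= 2:
        return BI_MODAL
    if start_peak:
        return EARLY
    if end_peak:
        return LATE
    return INTERMEDIATE


def assign_modes(
    consensus: ConsensusResult,
    centroids: np.ndarray | None = None,
    gene_ids=None,
    clustered: np.ndarray | None = None,
    expression: np.ndarray | None = None,
    flat_eps: float = 0.05,
    min_expression: float = 0.0,
) -> ModeMap:
    """Give every gene the mode of its consensus cluster's centroid.

    If ``clustered`` (the matrix the clustering ran on) is given, each
    consensus cluster's centroid is the mean trajectory of its member
    genes — the sharpest summary of what the consensus cluster is; run
    centroids averaged across alignments blur co-assigned shapes. Without
    it, ``centroids`` (defaulting to the aligned-mean run centroids) is
    classified instead. Genes whose maximum value in ``expression`` (the
    normalized, pre-peak-normalization matrix) falls below
    ``min_expression`` are UNCLASSIFIED regardless of cluster — too weakly
    expressed to call.
    """
    label_idx = consensus.consensus_label
    if centroids is None:
        if clustered is not None:
            X = np.asarray(clustered, dtype=float)
            centroids = consensus.consensus_centroids.copy()
            for j in range(centroids.shape[0]):
                members = label_idx == j
                if members.any():
                    centroids[j] = X[members].mean(axis=0)
        else:
            centroids = consensus.consensus_centroids
    centroids = np.asarray(centroids, dtype=float)
    cluster_mode = [classify_centroid_mode(c, flat_eps=flat_eps) for c in centroids]
    labels = [cluster_mode[j] for j in label_idx]
    n = len(labels)
    if gene_ids is None:
        gene_ids = pd.RangeIndex(n)
    labels = pd.Series(labels, index=pd.Index(gene_ids, name="gene"), dtype=object)
    if expression is not None and min_expression > 0:
        low = np.asarray(expression, dtype=float).max(axis=1) < min_expression
        labels[low] = UNCLASSIFIED
    return ModeMap(labels=labels, flat_eps=flat_eps)


def cluster_trajectories(
    t: TimeCourseMatrix,
    k: int | None = None,
    runs: int = 100,
    m: float = 1.25,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[list[FuzzyResult], ConsensusResult]:
    """Run seeded repeated fuzzy c-means on a (peak-normalized) time course.

    Run r uses seed ``seed + r``. ``k`` defaults to 3^(T-1), the number of
    possible sign paths of the trajectory.
    """
    X = t.values.to_numpy(dtype=float)
    T = X.shape[1]
    if k is None:
        k, _ = enumerate_paths(T)
    results = [
        fuzzy_cmeans(X, k=k, m=m, max_iter=max_iter, tol=tol, seed=seed + r)
        for r in range(runs)
    ]
    consensus = consensus_assignment(results)
    return results, consensus
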