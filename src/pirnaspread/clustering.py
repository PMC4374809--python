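"""Spreading-pattern clustering of gene bin vectors.

Genes with any antisense 22G signal are summarized as 10-bin vectors,
normalized to proportions (shape, not abundance), and grouped by k-means.
Per-cluster mutant/wild-type log-ratio curves then reveal directional loss:
a cluster whose 5' bins drop in a nuclear-RNAi mutant is called
``loss_5prime`` (distal small RNAs spreading 3'->5' from the piRNA site),
and symmetrically ``loss_3prime``.

The k-means here is Lloyd's algorithm with k-means++ seeding, written out
so that the convergence criterion used for choosing k is fully specified;
scikit-learn's implementation is used as an independent cross-check in the
tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LOSS_5PRIME = "loss_5prime"
LOSS_3PRIME = "loss_3prime"
NONE = "none"


@dataclass
class ClusterResult:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    seed: int
    converged: bool
    n_iter: int
    inertia: float
    objective_history: list[float] = field(default_factory=list)

    def genes_in(self, cluster_id: int) -> list[str]:
        return [g for g, c in self.assignments.items() if c == cluster_id]


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int,
           tol: float, rng: np.random.Generator):
    history = []
    labels = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(X.shape[0]), labels].sum()))
        new_centers = centers.copy()
        for j in range(centers.shape[0]):
            mask = labels == j
            if mask.any():
                new_centers[j] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster at the point farthest from its center
                far = d2[np.arange(X.shape[0]), labels].argmax()
                new_centers[j] = X[far]
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        if shift <= tol:
            converged = True
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return centers, labels, inertia, converged, n_iter, history


def kmeans(matrix: pd.DataFrame | np.ndarray, k: int, seed: int = 0,
           max_iter: int = 300, tol: float = 1e-6,
           n_init: int = 20,
           gene_ids: Sequence[str] | None = None) -> ClusterResult:
    """Lloyd's k-means with k-means++ seeding and ``n_init`` restarts.

    The restart with the lowest within-cluster sum of squares wins;
    ``converged`` reports whether that run's centroid shift fell below
    ``tol`` within ``max_iter`` iterations.  Fixed seed gives an identical
    result.
    """
    if isinstance(matrix, pd.DataFrame):
        gene_ids = list(matrix.index)
        X = matrix.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(matrix, dtype=np.float64)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(X.shape[0])]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError(f"need at least {k} distinct rows")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers0 = _kmeans_pp_init(X, k, rng)
        centers, labels, inertia, conv, n_iter, hist = _lloyd(
            X, centers0, max_iter, tol, rng)
        if best is None or inertia < best[2]:
            best = (centers, labels, inertia, conv, n_iter, hist)
    centers, labels, inertia, conv, n_iter, hist = best
    return ClusterResult(
        k=k, assignments=dict(zip(gene_ids, (int(c) for c in labels))),
        centroids=centers, seed=seed, converged=conv, n_iter=n_iter,
        inertia=inertia, objective_history=hist)


def select_k(matrix: pd.DataFrame | np.ndarray,
             k_range: Sequence[int] = range(2, 9), seed: int = 0,
             **kwargs) -> tuple[int, pd.DataFrame, dict[int, ClusterResult]]:
    """Run k-means over a range of k and keep the largest k that converged.

    Returns the chosen k, a per-k convergence report, and every fitted
    result so the caller need not re-run.
    """
    results: dict[int, ClusterResult] = {}
    rows = []
    for k in k_range:
        res = kmeans(matrix, k, seed=seed, **kwargs)
        results[k] = res
        rows.append({"k": k, "converged": res.converged,
                     "n_iter": res.n_iter, "inertia": res.inertia})
    report = pd.DataFrame(rows)
    converged_ks = [k for k in k_range if results[k].converged]
    if not converged_ks:
        raise RuntimeError("k-means failed to converge for every k in range")
    return max(converged_ks), report, results


def to_proportions(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene's bin vector to sum 1 so clusters capture shape.

    Zero-total genes must be excluded beforehand (they carry no shape)."""
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        bad = list(matrix.index[totals <= 0][:3])
        raise ValueError(f"zero-total genes present (e.g. {bad}); filter first")
    return matrix.div(totals, axis=0)


def filter_targeted(matrix: pd.DataFrame, min_reads: float = 1.0) -> pd.DataFrame:
    """Keep genes with at least ``min_reads`` raw antisense 22G reads."""
    return matrix.loc[matrix.sum(axis=1) >= min_reads]


@dataclass(frozen=True)
class RatioCurve:
    cluster_id: int
    values: np.ndarray  # log2(mutant/WT) per bin, 5'->3'
    n_genes: int


def ratio_curves(result: ClusterResult, mutant_bins: pd.DataFrame,
                 wt_bins: pd.DataFrame, library_sizes: tuple[float, float],
                 pseudocount: float = 1.0) -> list[RatioCurve]:
    """Per-cluster log2(mutant/WT) of the average library-normalized bin value.

    For each cluster the bin values are averaged over its genes in each
    condition, each condition scaled by its total library size (reads per
    million), and the mutant average divided by the wild-type average;
    ``pseudocount`` (reads per million) keeps the log finite.
    """
    genes = list(result.assignments)
    missing = [g for g in genes if g not in mutant_bins.index or g not in wt_bins.index]
    if missing:
        raise ValueError(f"genes missing from bin matrices: {missing[:3]}")
    lib_mut, lib_wt = library_sizes
    mut_rpm = mutant_bins.loc[genes] * 1e6 / lib_mut
    wt_rpm = wt_bins.loc[genes] * 1e6 / lib_wt
    labels = pd.Series({g: result.assignments[g] for g in genes})
    curves = []
    for cid in sorted(set(labels)):
        members = labels.index[labels == cid]
        if len(members) == 0:
            raise ValueError(f"empty cluster {cid}")
        mean_mut = mut_rpm.loc[members].mean(axis=0).to_numpy()
        mean_wt = wt_rpm.loc[members].mean(axis=0).to_numpy()
        vals = np.log2((mean_mut + pseudocount) / (mean_wt + pseudocount))
        curves.append(RatioCurve(int(cid), vals, int(len(members))))
    return curves


@dataclass(frozen=True)
class SpreadingCall:
    cluster_id: int
    index: float
    label: str


def call_spreading(curves: Sequence[RatioCurve],
                   threshold: float = 0.5) -> list[SpreadingCall]:
    """Classify each cluster's ratio curve by spreading direction.

    The spreading index is mean(5'-half bins) - mean(3'-half bins) of the
    log2 ratio curve; an index below -threshold means the mutant lost 22Gs
    preferentially at the 5' end (3'->5' spreading in the wild type).
    """
    calls = []
    for c in curves:
        if not np.isfinite(c.values).all():
            raise ValueError(f"cluster {c.cluster_id}: non-finite curve")
        half = c.values.size // 2
        index = float(c.values[:half].mean() - c.values[half:].mean())
        if index < -threshold:
            label = LOSS_5PRIME
        elif index > threshold:
            label = LOSS_3PRIME
        else:
            label = NONE
        calls.append(SpreadingCall(c.cluster_id, index, label))
    return calls


from sklearn.base import BaseEstimator, ClusterMixin


class SpreadingKMeans(ClusterMixin, BaseEstimator):
    """Scikit-learn estimator front end to the shape clustering.

    fit(X) accepts a genes x bins matrix (DataFrame or array), optionally
    row-normalizes to proportions, and exposes ``cluster_centers_``,
    ``labels_``, ``inertia_``, ``n_iter_`` and ``converged_``.
    """

    def __init__(self, n_clusters: int = 7, random_state: int = 0,
                 max_iter: int = 300, tol: float = 1e-6, n_init: int = 20,
                 scale_to_proportions: bool = True):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.scale_to_proportions = scale_to_proportions

    def _prepare(self, X) -> np.ndarray:
        A = X.to_numpy(dtype=np.float64) if isinstance(X, pd.DataFrame) \
            else np.asarray(X, dtype=np.float64)
        if A.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.scale_to_proportions:
            totals = A.sum(axis=1)
            if (totals <= 0).any():
                raise ValueError("zero-total rows cannot be scaled to proportions")
            A = A / totals[:, None]
        return A

    def fit(self, X, y=None) -> "SpreadingKMeans":
        A = self._prepare(X)
        ids = list(X.index) if isinstance(X, pd.DataFrame) else None
        res = kmeans(A, self.n_clusters, seed=self.random_state,
                     max_iter=self.max_iter, tol=self.tol, n_init=self.n_init,
                     gene_ids=ids)
        self.result_ = res
        self.cluster_centers_ = res.centroids
        self.labels_ = np.array([res.assignments[g] for g in res.assignments])
        self.inertia_ = res.inertia
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "cluster_centers_"):
            raise RuntimeError("fit before predict")
        A = self._prepare(X)
        d2 = ((A[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)
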