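"""Profile extraction: k-means on the SOM codebook with Davies-Bouldin
selection of the cluster count, and propagation of neuron labels to
participants through their best-matching units.

The clustering operates on the neural weight vectors, not directly on the
participants; each participant inherits the cluster of its BMU.  The
candidate cluster counts k = 2..10 are scored by the Davies-Bouldin index
(lower = more distinct clusters) and the minimizer is chosen, preferring
the smaller k on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .som import TrainedSOM, bmu_pairs

__all__ = [
    "ClusterSolution",
    "kmeans_codebook",
    "davies_bouldin",
    "choose_k",
    "assign_participants",
    "cluster_summary",
]


@dataclass
class ClusterSolution:
    k: int
    neuron_labels: np.ndarray  # cluster id per neuron
    centroids: np.ndarray  # (k, dim) mean weight vectors
    db_trace: dict[int, float]  # Davies-Bouldin value per candidate k
    participant_labels: np.ndarray | None = None  # cluster id per participant
    hits: np.ndarray | None = None  # participants per neuron

    @property
    def cluster_sizes(self) -> np.ndarray:
        if self.participant_labels is None:
            raise ValueError("participants not assigned yet")
        return np.bincount(self.participant_labels, minlength=self.k)


def kmeans_codebook(
    codebook: np.ndarray, k: int, restarts: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts Lloyd k-means on the neuron weight vectors.

    Returns (labels, centroids, within-cluster sum of squares).
    """
    codebook = np.asarray(codebook, dtype=float)
    if not 1 <= k <= codebook.shape[0]:
        raise ValueError(
            f"k={k} out of range for a codebook of {codebook.shape[0]} neurons"
        )
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(codebook)
    return km.labels_.astype(int), km.cluster_centers_, float(km.inertia_)


def davies_bouldin(
    points: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> float:
    """Davies-Bouldin index: mean over clusters of the worst similarity
    ratio (S_i + S_j) / M_ij, where S_i is the mean Euclidean distance of
    cluster i's members to its centroid and M_ij the centroid distance.

    Raises on empty clusters and on coincident centroids (the ratio is
    undefined there).
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    centroids = np.asarray(centroids, dtype=float)
    k = centroids.shape[0]
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least 2 clusters")
    scatters = np.empty(k)
    for i in range(k):
        members = points[labels == i]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {i} is empty")
        scatters[i] = np.linalg.norm(members - centroids[i], axis=1).mean()
    diff = centroids[:, None, :] - centroids[None, :, :]
    m = np.sqrt((diff**2).sum(axis=2))
    total = 0.0
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            if m[i, j] == 0.0:
                raise ValueError(f"clusters {i} and {j} have coincident centroids")
            ratios.append((scatters[i] + scatters[j]) / m[i, j])
        total += max(ratios)
    return total / k


def choose_k(
    codebook: np.ndarray,
    k_range: range = range(2, 11),
    restarts: int = 100,
    seed: int = 0,
) -> ClusterSolution:
    """Scan candidate cluster counts and keep the Davies-Bouldin minimizer.

    Ties go to the smaller k (fewer profiles).  Candidate counts whose
    k-means solution is degenerate (empty cluster or coincident centroids)
    are recorded as NaN and skipped; if all candidates fail the codebook
    is unusable and an error is raised.
    """
    codebook = np.asarray(codebook, dtype=float)
    db_trace: dict[int, float] = {}
    solutions: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in k_range:
        try:
            labels, centroids, _ = kmeans_codebook(codebook, k, restarts, seed)
            db_trace[k] = davies_bouldin(codebook, labels, centroids)
            solutions[k] = (labels, centroids)
        except ValueError:
            db_trace[k] = float("nan")
    finite = {k: v for k, v in db_trace.items() if np.isfinite(v)}
    if not finite:
        raise RuntimeError("no candidate cluster count produced a valid solution")
    best_k = min(finite, key=lambda k: (finite[k], k))
    labels, centroids = solutions[best_k]
    return ClusterSolution(
        k=best_k, neuron_labels=labels, centroids=centroids, db_trace=db_trace
    )


def assign_participants(
    som: TrainedSOM, solution: ClusterSolution, data: np.ndarray
) -> ClusterSolution:
    """Propagate neuron cluster labels to participants via their BMUs.

    Also records hits (participants per neuron, the 'neuron shadows').
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] != som.weights.shape[1]:
        raise ValueError(
            f"data dimension {data.shape[1]} does not match codebook "
            f"dimension {som.weights.shape[1]}"
        )
    winners, _ = bmu_pairs(som.weights, data)
    solution.participant_labels = solution.neuron_labels[winners]
    solution.hits = np.bincount(winners, minlength=som.grid.n_units)
    return solution


def cluster_summary(
    cohort: pd.DataFrame,
    solution: ClusterSolution,
    variables: list[str],
) -> pd.DataFrame:
    """Per-cluster median and IQR of each variable on its native scale.

    Quartiles use linear interpolation.  Returns a tidy frame indexed by
    variable with one (median, iqr) column pair per cluster.  Empty
    clusters yield NaN columns with a warning.
    """
    import warnings

    if solution.participant_labels is None:
        raise ValueError("assign_participants must run before cluster_summary")
    labels = solution.participant_labels
    rows = {}
    for cluster in range(solution.k):
        members = cohort.loc[labels == cluster, variables]
        if members.empty:
            warnings.warn(f"cluster {cluster} has no participants")
            rows[f"c{cluster}_median"] = pd.Series(np.nan, index=variables)
            rows[f"c{cluster}_iqr"] = pd.Series(np.nan, index=variables)
            continue
        q1 = members.quantile(0.25)
        q3 = members.quantile(0.75)
        rows[f"c{cluster}_median"] = members.median()
        rows[f"c{cluster}_iqr"] = q3 - q1
    out = pd.DataFrame(rows)
    out.index.name = "variable"
    return out
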