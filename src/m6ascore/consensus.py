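"""Resampling-based consensus clustering of samples.

Implements the Monti-style procedure: for each candidate k, samples are
repeatedly subsampled (80% by default) and clustered; the consensus matrix
records how often each pair co-clusters among the draws in which both were
sampled.  Cluster-number diagnostics are the CDF area of consensus entries,
its relative increase (delta area) and the proportion of ambiguous
clustering (PAC).

The inner clustering is hierarchical with average linkage on 1 - Pearson
correlation distance between samples, matching the conventional defaults of
the consensus-clustering procedure this mirrors; k-means on Euclidean
distance is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["inner_cluster", "ConsensusClustering", "ConsensusResult", "select_k"]


def _sample_distance(x_sub: np.ndarray, distance: str) -> np.ndarray:
    """Condensed distance between columns (samples) of a features x samples block."""
    if distance == "pearson":
        d = pdist(x_sub.T, metric="correlation")
        # zero-variance samples yield nan correlation; treat as maximally distant
        return np.nan_to_num(d, nan=1.0)
    if distance == "euclidean":
        return pdist(x_sub.T, metric="euclidean")
    raise ValueError(f"unknown distance {distance!r}")


def inner_cluster(
    x_sub: np.ndarray,
    k: int,
    method: str = "hierarchical",
    distance: str = "pearson",
    seed: int | None = None,
) -> np.ndarray:
    """Cluster the columns of ``x_sub`` into k groups; deterministic given seed.

    Hierarchical clustering uses average linkage on the chosen sample distance.
    Ties (identical samples) break deterministically by sample order through
    scipy's stable linkage ordering.
    """
    n = x_sub.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if method == "hierarchical":
        z = linkage(_sample_distance(x_sub, distance), method="average")
        return fcluster(z, t=k, criterion="maxclust")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        return km.fit_predict(x_sub.T) + 1
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, labels and k-selection diagnostics."""

    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    labels: dict[int, pd.Series]
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int
    n_never_cosampled: int = 0
    params: dict = field(default_factory=dict)

    def labels_for(self, k: int | None = None) -> pd.Series:
        return self.labels[self.chosen_k if k is None else k]

    def summary(self) -> pd.DataFrame:
        """Per-k diagnostics table (CDF area, delta area, PAC, cluster sizes)."""
        rows = []
        for k in sorted(self.consensus):
            sizes = self.labels[k].value_counts().sort_index().tolist()
            rows.append(
                {
                    "k": k,
                    "cdf_area": self.cdf_area[k],
                    "delta_area": self.delta_area[k],
                    "pac": self.pac[k],
                    "cluster_sizes": sizes,
                    "chosen": k == self.chosen_k,
                }
            )
        return pd.DataFrame(rows).set_index("k")

    def plot_cdf(self, ax=None):
        """Empirical CDFs of consensus entries, one curve per k."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for k, mat in sorted(self.consensus.items()):
            vals = np.sort(mat[np.triu_indices_from(mat, k=1)])
            ax.step(vals, np.arange(1, len(vals) + 1) / len(vals), label=f"k={k}")
        ax.set_xlabel("consensus value")
        ax.set_ylabel("CDF")
        ax.legend()
        return ax


class ConsensusClustering:
    """Consensus clustering model over a features x samples matrix.

    Parameters
    ----------
    data : DataFrame
        Features (e.g. the regulator panel) in rows, samples in columns.
    k_range : iterable of int
        Candidate cluster numbers, each >= 2.
    reps : int
        Number of subsampling repetitions per k (1000 for production runs;
        smaller values are adequate for strongly structured data).
    p_item : float
        Fraction of samples drawn (without replacement) per repetition.
    seed : int
        Base seed; each (k, rep) draw uses a counter-derived child seed so
        results are reproducible under any execution order.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        k_range=range(2, 7),
        reps: int = 1000,
        p_item: float = 0.8,
        seed: int = 0,
        method: str = "hierarchical",
        distance: str = "pearson",
        rule: str = "delta_area",
    ):
        self.data = data
        self.k_range = sorted(set(int(k) for k in k_range))
        self.reps = int(reps)
        self.p_item = float(p_item)
        self.seed = int(seed)
        self.method = method
        self.distance = distance
        self.rule = rule
        n = data.shape[1]
        if data.shape[0] < 2:
            raise ValueError("need at least 2 features")
        if min(self.k_range) < 2:
            raise ValueError("k must be >= 2")
        if n < max(self.k_range) + 1:
            raise ValueError("need at least max(k_range)+1 samples")
        if not 0 < self.p_item <= 1:
            raise ValueError("p_item must be in (0, 1]")

    def fit(self) -> ConsensusResult:
        x = self.data.to_numpy(dtype=float)
        n = x.shape[1]
        sub_n = int(np.ceil(self.p_item * n))
        consensus: dict[int, np.ndarray] = {}
        labels: dict[int, pd.Series] = {}
        pac: dict[int, float] = {}
        cdf_area: dict[int, float] = {}
        never = 0
        for k in self.k_range:
            hits = np.zeros((n, n))
            draws = np.zeros((n, n))
            for rep in range(self.reps):
                rng = np.random.default_rng(
                    np.random.SeedSequence(self.seed, spawn_key=(k, rep))
                )
                idx = np.sort(rng.choice(n, size=sub_n, replace=False))
                lab = inner_cluster(x[:, idx], k, self.method, self.distance, seed=rep)
                same = lab[:, None] == lab[None, :]
                draws[np.ix_(idx, idx)] += 1
                hits[np.ix_(idx, idx)] += same
            with np.errstate(invalid="ignore", divide="ignore"):
                mat = np.where(draws > 0, hits / np.maximum(draws, 1), 0.0)
            pair_never = int((draws[np.triu_indices(n, k=1)] == 0).sum())
            if pair_never:
                logger.warning("consensus k=%d: %d pairs never co-sampled (set to 0)", k, pair_never)
                never += pair_never
            np.fill_diagonal(mat, 1.0)
            mat = (mat + mat.T) / 2
            consensus[k] = mat
            # final labels: hierarchical clustering of consensus dissimilarity
            z = linkage(squareform(1.0 - mat, checks=False), method="average")
            lab_final = fcluster(z, t=k, criterion="maxclust")
            labels[k] = pd.Series(lab_final, index=self.data.columns, name=f"k{k}")
            off = mat[np.triu_indices(n, k=1)]
            pac[k] = float(np.mean((off > 0.1) & (off <= 0.9)))
            # area under the empirical CDF on [0,1] equals 1 - mean(entries)
            cdf_area[k] = float(1.0 - off.mean())
        delta_area: dict[int, float] = {}
        ks = self.k_range
        delta_area[ks[0]] = cdf_area[ks[0]]
        for prev, k in zip(ks, ks[1:]):
            base = cdf_area[prev]
            delta_area[k] = (cdf_area[k] - base) / base if base > 0 else 0.0
        result = ConsensusResult(
            sample_ids=self.data.columns.tolist(),
            consensus=consensus,
            labels=labels,
            cdf_area=cdf_area,
            delta_area=delta_area,
            pac=pac,
            chosen_k=0,
            n_never_cosampled=never,
            params={
                "reps": self.reps,
                "p_item": self.p_item,
                "seed": self.seed,
                "method": self.method,
                "distance": self.distance,
            },
        )
        result.chosen_k = select_k(result, rule=self.rule)
        return result


def select_k(result: ConsensusResult, rule: str = "delta_area", threshold: float = 0.1) -> int:
    """Choose the number of clusters from consensus diagnostics.

    delta_area: the largest k whose relative CDF-area increase over the
    previous k exceeds ``threshold`` (the smallest k always qualifies);
    pac: argmin of the proportion of ambiguous clustering, ties to smaller k.
    A PAC above 0.5 at the chosen k is flagged as low-confidence.
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        return ks[0]
    if rule == "delta_area":
        chosen = ks[0]
        for k in ks[1:]:
            if result.delta_area[k] > threshold:
                chosen = k
    elif rule == "pac":
        chosen = min(ks, key=lambda k: (result.pac[k], k))
    else:
        raise ValueError(f"unknown k-selection rule {rule!r}")
    if result.pac[chosen] > 0.5:
        logger.warning("select_k: PAC=%.2f at k=%d — low-confidence clustering", result.pac[chosen], chosen)
    return chosen
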