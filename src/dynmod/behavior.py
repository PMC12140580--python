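"""Learning measures, learner subgrouping, and the PC1 behavioral proxy.

Trial tables from a visuomotor-rotation task (45° cursor rotation, 40
learning bins of 8 trials per day) are reduced to five per-subject
measures: early/late error on each day (mean binned median error over
bins 1–3 and 38–40) and savings (day-1 early minus day-2 early).
Subjects are subgrouped by k-means over the five measures with many
random restarts, validated with the Silhouette and Caliński-Harabasz
indices and a multivariate-normal significance null; the sign-fixed
first principal component of the measures is the scalar learning
outcome used for brain-behavior regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from ._seeds import derive_rng

__all__ = [
    "LearningMeasures",
    "BehavioralEmbedding",
    "ClusteringResult",
    "binned_median_error",
    "learning_measures",
    "cluster_participants",
    "clustering_significance",
    "behavioral_pc1",
]

EARLY_BINS = (1, 2, 3)
LATE_BINS = (38, 39, 40)
N_LEARNING_BINS = 40
TRIALS_PER_BIN = 8

MEASURE_NAMES = ("early1", "late1", "early2", "late2", "savings")


@dataclass(frozen=True)
class LearningMeasures:
    """Per-subject early/late error (degrees) per day and savings."""

    early1: float
    late1: float
    early2: float
    late2: float
    savings: float

    def __post_init__(self) -> None:
        if not np.isclose(self.savings, self.early1 - self.early2):
            raise ValueError("savings must equal early1 - early2")

    def as_array(self) -> np.ndarray:
        return np.array([self.early1, self.late1, self.early2, self.late2, self.savings])


@dataclass
class ClusteringResult:
    """Best k-means labels per k with validity indices and the agreed k."""

    labels_by_k: dict[int, np.ndarray]
    silhouette: dict[int, float]
    calinski_harabasz: dict[int, float]
    inertia_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def k_by_silhouette(self) -> int:
        return max(self.silhouette, key=self.silhouette.get)

    @property
    def k_by_calinski_harabasz(self) -> int:
        return max(self.calinski_harabasz, key=self.calinski_harabasz.get)

    @property
    def indices_agree(self) -> bool:
        return self.k_by_silhouette == self.k_by_calinski_harabasz

    @property
    def selected_k(self) -> int:
        """The k both indices agree on; raises loudly on disagreement."""
        if not self.indices_agree:
            raise ValueError(
                "cluster validity indices disagree: "
                f"Silhouette selects k={self.k_by_silhouette}, "
                f"Caliński-Harabasz selects k={self.k_by_calinski_harabasz}"
            )
        return self.k_by_silhouette

    @property
    def labels(self) -> np.ndarray:
        return self.labels_by_k[self.selected_k]


@dataclass
class BehavioralEmbedding:
    """Sign-fixed PC1 scores, loadings, and explained-variance fractions."""

    pc1: np.ndarray
    loadings: np.ndarray           # 5×n_components
    explained_variance: np.ndarray
    scores: np.ndarray             # n_subjects×n_components (PC1 sign-fixed)


def binned_median_error(trials: pd.DataFrame, day: int | None = None) -> pd.Series:
    """Per-bin median endpoint error of the learning block.

    ``trials`` has columns day, trial, bin, target_deg, error_deg;
    discarded trials are simply absent rows (medians use what remains).
    """
    t = trials if day is None else trials[trials["day"] == day]
    if t.empty:
        raise ValueError("no trials" + ("" if day is None else f" for day {day}"))
    med = t.groupby("bin")["error_deg"].median()
    expected = set(range(1, N_LEARNING_BINS + 1))
    missing = sorted(expected - set(med.index))
    if missing:
        raise ValueError(f"empty learning bins: {missing}")
    return med.sort_index()


def learning_measures(bins_day1: pd.Series, bins_day2: pd.Series) -> LearningMeasures:
    """Early/late/savings from the two days' binned medians."""
    for name, b in (("day 1", bins_day1), ("day 2", bins_day2)):
        if not set(EARLY_BINS + LATE_BINS) <= set(b.index):
            raise ValueError(f"missing early/late bins for {name}")
    early1 = float(bins_day1.loc[list(EARLY_BINS)].mean())
    late1 = float(bins_day1.loc[list(LATE_BINS)].mean())
    early2 = float(bins_day2.loc[list(EARLY_BINS)].mean())
    late2 = float(bins_day2.loc[list(LATE_BINS)].mean())
    return LearningMeasures(
        early1=early1, late1=late1, early2=early2, late2=late2, savings=early1 - early2
    )


def measures_matrix(measures: list[LearningMeasures]) -> np.ndarray:
    return np.stack([m.as_array() for m in measures])


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance measure columns: {np.flatnonzero(sd == 0).tolist()}")
    return (X - X.mean(axis=0)) / sd


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    """One k-means run from a random k-distinct-points init; returns
    (labels, total within-cluster sum of distances to assigned centroids —
    the objective Lloyd iterations minimize)."""
    n = X.shape[0]
    centroids = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(k):
            mask = labels == c
            if mask.any():
                centroids[c] = X[mask].mean(axis=0)
            else:  # re-seed an emptied cluster at the farthest point
                centroids[c] = X[d2.min(axis=1).argmax()]
    return labels, float(((X - centroids[labels]) ** 2).sum())


def cluster_participants(
    X: np.ndarray,
    k_range=range(2, 10),
    restarts: int = 1000,
    max_iter: int = 10_000,
    seed: int = 0,
    standardize: bool = True,
) -> ClusteringResult:
    """k-means sweep over ``k_range``, keeping the best restart per k.

    The restart with the lowest sum of Euclidean distances between
    points and assigned centroids wins; every k is scored with both the
    Silhouette and Caliński-Harabasz indices.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("measures must be an n_subjects × n_measures matrix")
    n = X.shape[0]
    Xs = _standardize(X) if standardize else X
    labels_by_k, sil, ch, inertia = {}, {}, {}, {}
    for k in k_range:
        if k > n:
            raise ValueError(f"k={k} exceeds n={n} subjects")
        best = None
        for r in range(restarts):
            rng = derive_rng(seed, "kmeans", k, r)
            labels, cost = _lloyd(Xs, k, rng, max_iter)
            if best is None or cost < best[1]:
                best = (labels, cost)
        labels, cost = best
        if len(np.unique(labels)) < 2:
            continue  # degenerate solution: indices undefined
        labels_by_k[k] = labels
        inertia[k] = cost
        sil[k] = float(silhouette_score(Xs, labels))
        ch[k] = float(calinski_harabasz_score(Xs, labels))
    if not labels_by_k:
        raise ValueError("no non-degenerate clustering found in k_range")
    return ClusteringResult(
        labels_by_k=labels_by_k, silhouette=sil, calinski_harabasz=ch, inertia_by_k=inertia
    )


def clustering_significance(
    X: np.ndarray,
    n_iter: int = 1000,
    k_range=range(2, 10),
    restarts: int = 1000,
    max_iter: int = 10_000,
    seed: int = 0,
    standardize: bool = True,
) -> dict:
    """Multivariate-normal null for the cluster-validity indices.

    Each iteration draws n subjects from N(mean, cov) of the data, runs
    the same k-means sweep, and records the maximum of each index over
    k; p (per index) is the proportion of iterations whose maximum
    exceeds the observed maximum.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    X = np.asarray(X, dtype=float)
    obs = cluster_participants(
        X, k_range, restarts, max_iter, seed=seed, standardize=standardize
    )
    obs_sil = max(obs.silhouette.values())
    obs_ch = max(obs.calinski_harabasz.values())
    mean, cov = X.mean(axis=0), np.cov(X, rowvar=False)
    shrunk = False
    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        cov = cov + 1e-8 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
        shrunk = True
    rng = derive_rng(seed, "cluster-null")
    exceed_sil = exceed_ch = 0
    for it in range(n_iter):
        Xn = rng.multivariate_normal(mean, cov, size=X.shape[0], method="cholesky")
        try:
            null = cluster_participants(
                Xn, k_range, restarts, max_iter,
                seed=int(rng.integers(2**31)), standardize=standardize,
            )
        except ValueError:
            continue
        if max(null.silhouette.values()) > obs_sil:
            exceed_sil += 1
        if max(null.calinski_harabasz.values()) > obs_ch:
            exceed_ch += 1
    return {
        "p_silhouette": exceed_sil / n_iter,
        "p_calinski_harabasz": exceed_ch / n_iter,
        "observed_silhouette": obs_sil,
        "observed_calinski_harabasz": obs_ch,
        "covariance_shrunk": shrunk,
    }


def behavioral_pc1(X: np.ndarray, standardize: bool = True) -> BehavioralEmbedding:
    """PCA of the five learning measures with the fast-learning sign fix.

    PC1's sign is chosen so higher scores mean faster learning, i.e. its
    correlation with mean early error across days is negative.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects for PCA")
    Xs = _standardize(X) if standardize else X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    scores = U * s
    evr = s**2 / np.sum(s**2)
    early_mean = X[:, [0, 2]].mean(axis=1)  # early1, early2
    r = np.corrcoef(scores[:, 0], early_mean)[0, 1]
    if r > 0:
        scores[:, 0] = -scores[:, 0]
        Vt[0] = -Vt[0]
    return BehavioralEmbedding(
        pc1=scores[:, 0], loadings=Vt.T, explained_variance=evr, scores=scores
    )
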