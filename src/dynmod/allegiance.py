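"""Module allegiance matrices and network-level summaries.

The allegiance matrix P gives, for each pair of regions, the probability
of co-assignment to the same module, pooled over time slices, partitions
and (optionally) subjects: T counts co-assignments, C is the total
number of slices counted, and P = T / C.  Given a hard assignment of
regions to K labeled networks, block means of P yield:

- interaction      I_{k1,k2} = (Σ_{i∈C_k1, j∈C_k2} P_ij) / (|C_k1||C_k2|)
- recruitment      I_{k,k} (within-network allegiance)
- integration      I′_{k1,k2} = I_{k1,k2} / sqrt(I_{k1,k1} · I_{k2,k2})

plus Jaccard set similarity (×100) and Pearson correlation of the
off-diagonal entries of two allegiance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .modularity import PartitionEnsemble

__all__ = [
    "AllegianceMatrix",
    "NetworkAssignment",
    "module_allegiance",
    "interaction",
    "recruitment",
    "integration",
    "jaccard_similarity",
    "allegiance_similarity",
]


@dataclass
class AllegianceMatrix:
    """P = T/C with co-assignment counts T and slice-count normalizer C."""

    P: np.ndarray
    T: np.ndarray
    C: int
    scope: str = "subject"

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.P.shape != self.T.shape or self.P.ndim != 2:
            raise ValueError("P and T must be matching square matrices")

    @property
    def n_regions(self) -> int:
        return self.P.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of unordered off-diagonal region pairs, N(N−1)/2."""
        n = self.n_regions
        return n * (n - 1) // 2


@dataclass
class NetworkAssignment:
    """Hard region→network labeling (labels 1..K; every network nonempty)."""

    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D region vector")

    def members(self, k: int) -> np.ndarray:
        idx = np.flatnonzero(self.labels == k)
        if idx.size == 0:
            raise ValueError(f"empty community: no region has label {k}")
        return idx

    @property
    def networks(self) -> np.ndarray:
        return np.unique(self.labels)


def _null_threshold_coassignment(
    module_sizes_per_slice: list[np.ndarray],
    n_regions: int,
    n_draws: int,
    percentile: float,
    rng: np.random.Generator,
) -> float:
    """95th percentile of null P_ij under within-slice label permutation.

    Permuting labels within a slice makes the co-assignment of a fixed
    region pair a Bernoulli draw with success probability
    q = Σ_k n_k(n_k−1) / (N(N−1)) — identical for all pairs — so the null
    distribution of P_ij is a mean of independent Bernoullis, simulated
    directly without materializing permuted matrices.
    """
    q = np.array(
        [float((s * (s - 1)).sum()) / (n_regions * (n_regions - 1)) for s in module_sizes_per_slice]
    )
    draws = (rng.random((n_draws, q.size)) < q).mean(axis=1)
    return float(np.percentile(draws, percentile))


def module_allegiance(
    ensembles: PartitionEnsemble | list[PartitionEnsemble],
    null_zero: bool = False,
    n_null: int = 1000,
    percentile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> AllegianceMatrix:
    """Co-assignment probability over all slices × partitions × subjects.

    Counts are pooled before normalizing (group scope), so a pooled run
    equals the slice-count-weighted average of per-subject matrices.
    With ``null_zero``, off-diagonal entries not exceeding the permutation
    -null percentile are set to 0; the diagonal (P_ii = 1) is exempt.
    """
    if isinstance(ensembles, PartitionEnsemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("no ensembles given")
    n = ensembles[0].partitions[0].n_regions
    T = np.zeros((n, n))
    C = 0
    sizes: list[np.ndarray] = []
    for ens in ensembles:
        for part in ens.partitions:
            if part.n_regions != n:
                raise ValueError("mismatched region sets across ensembles")
            for l in range(part.n_layers):
                lab = part.labels[l]
                T += lab[:, None] == lab[None, :]
                C += 1
                sizes.append(np.bincount(lab))
    P = T / C
    if null_zero:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        thr = _null_threshold_coassignment(sizes, n, n_null, percentile, rng)
        off = ~np.eye(n, dtype=bool)
        P = P.copy()
        P[off & (P <= thr)] = 0.0
    scope = "group" if (len(ensembles) > 1) else "subject"
    return AllegianceMatrix(P=P, T=T, C=C, scope=scope)


def interaction(P: AllegianceMatrix, k1: int, k2: int, assign: NetworkAssignment) -> float:
    """Mean allegiance over the C_k1 × C_k2 block (diagonal included when k1=k2)."""
    a = assign.members(k1)
    b = assign.members(k2)
    return float(P.P[np.ix_(a, b)].mean())


def recruitment(
    P: AllegianceMatrix, k: int, assign: NetworkAssignment, include_diagonal: bool = True
) -> float:
    """Within-network allegiance I_{k,k}.

    The printed block-mean formula sums all (i, j) including i = j; set
    ``include_diagonal=False`` for the off-diagonal-only variant.
    """
    if include_diagonal:
        return interaction(P, k, k, assign)
    a = assign.members(k)
    block = P.P[np.ix_(a, a)]
    m = a.size
    if m < 2:
        raise ValueError("off-diagonal recruitment undefined for a singleton community")
    return float((block.sum() - np.trace(block)) / (m * (m - 1)))


def integration(P: AllegianceMatrix, k1: int, k2: int, assign: NetworkAssignment) -> float:
    """Normalized between-network interaction I′ = I_{k1,k2} / √(I_k1k1 I_k2k2).

    May exceed 1; not clamped.
    """
    if k1 == k2:
        raise ValueError("integration is defined for distinct networks")
    r1 = interaction(P, k1, k1, assign)
    r2 = interaction(P, k2, k2, assign)
    if r1 <= 0 or r2 <= 0:
        raise ValueError("undefined normalization: zero recruitment")
    return interaction(P, k1, k2, assign) / float(np.sqrt(r1 * r2))


def jaccard_similarity(set_a, set_b) -> float:
    """100 · |A∩B| / |A∪B|."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("both sets empty")
    return 100.0 * len(a & b) / len(union)


def allegiance_similarity(P1: AllegianceMatrix, P2: AllegianceMatrix) -> float:
    """Pearson correlation of the unordered off-diagonal entries of two P matrices."""
    if P1.n_regions != P2.n_regions:
        raise ValueError("mismatched region sets")
    iu = np.triu_indices(P1.n_regions, k=1)
    v1, v2 = P1.P[iu], P2.P[iu]
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("zero variance in allegiance entries")
    return float(sp_stats.pearsonr(v1, v2).statistic)
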