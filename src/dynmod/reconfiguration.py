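"""Coordinated vs. uncoordinated modular reconfiguration.

For each transition between consecutive windows, a region may keep its
module, move together with partners (same source module AND same target
module), or move alone.  Two per-region summaries over the L−1
transitions of a partition:

- **cohesion strength** — number of times the region changes modules
  together with each other region, summed over all other regions,
  divided by the number of transitions (unbounded above);
- **disjointedness** — fraction of transitions in which the region
  changes modules with no partner making the same source→target move
  (in [0, 1]).

Module identity across layers comes from the multilayer partition labels
themselves; no relabeling step is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modularity import Partition, PartitionEnsemble

__all__ = ["ReconfigScores", "cohesion_strength", "disjointedness", "ensemble_reconfig"]


@dataclass
class ReconfigScores:
    """Per-region reconfiguration scores plus subject-level means."""

    cohesion: np.ndarray
    disjointedness: np.ndarray

    @property
    def mean_cohesion(self) -> float:
        return float(self.cohesion.mean())

    @property
    def mean_disjointedness(self) -> float:
        return float(self.disjointedness.mean())


def _transition_moves(src: np.ndarray, dst: np.ndarray):
    """For one transition: per-region partner counts of identical
    (source, target) moves, and the mask of regions that changed."""
    changed = src != dst
    idx = np.flatnonzero(changed)
    if idx.size == 0:
        return idx, np.zeros(0, dtype=int)
    moves = src[idx].astype(np.int64) * (max(dst.max(), src.max()) + 1) + dst[idx]
    _, inverse, counts = np.unique(moves, return_inverse=True, return_counts=True)
    return idx, counts[inverse]


def cohesion_strength(partition: Partition) -> np.ndarray:
    """Per-region mutual module changes per transition (summed over partners)."""
    labels = partition.labels
    L = labels.shape[0]
    if L < 2:
        raise ValueError("no transitions: partition has fewer than 2 layers")
    coh = np.zeros(labels.shape[1])
    for t in range(L - 1):
        idx, group_sizes = _transition_moves(labels[t], labels[t + 1])
        if idx.size:
            coh[idx] += group_sizes - 1  # partners making the same move
    return coh / (L - 1)


def disjointedness(partition: Partition) -> np.ndarray:
    """Per-region fraction of transitions with a lone module change."""
    labels = partition.labels
    L = labels.shape[0]
    if L < 2:
        raise ValueError("no transitions: partition has fewer than 2 layers")
    dis = np.zeros(labels.shape[1])
    for t in range(L - 1):
        idx, group_sizes = _transition_moves(labels[t], labels[t + 1])
        if idx.size:
            dis[idx[group_sizes == 1]] += 1
    return dis / (L - 1)


def ensemble_reconfig(ensemble: PartitionEnsemble) -> ReconfigScores:
    """Average the per-region scores over all partitions of an ensemble.

    The subject scalar (mean over regions of the per-region means) is
    exposed on the returned :class:`ReconfigScores`; by linearity it does
    not depend on the averaging order.
    """
    if ensemble.n_partitions == 0:
        raise ValueError("empty ensemble")
    coh = np.mean([cohesion_strength(p) for p in ensemble.partitions], axis=0)
    dis = np.mean([disjointedness(p) for p in ensemble.partitions], axis=0)
    return ReconfigScores(cohesion=coh, disjointedness=dis)
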