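"""Symmetric nonnegative matrix factorization of allegiance matrices.

Approximates a symmetric nonnegative Y as H Hᵀ with H ≥ 0 (N×r) by
minimizing f(H) = ‖Y − HHᵀ‖²_F.  The optimizer is a Newton-like
curvature-scaled projected-gradient scheme: Barzilai–Borwein secant
steps (a diagonal Hessian surrogate) with Armijo backtracking along the
projection arc, which enforces a monotone loss decrease.  Each fit is
repeated from many uniform-[0,1] initializations and the best final loss
wins; rank selection reports mean RMSE, the dispersion coefficient and
cophenetic correlation of the across-init consensus, and explained
variance per rank.  Hard communities come from each region's strongest
factor loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from ._seeds import derive_rng
from .allegiance import NetworkAssignment

__all__ = ["SymNMFResult", "RankSelection", "symnmf", "rank_selection", "assign_clusters"]


@dataclass
class SymNMFResult:
    """Best-of-inits factorization: factors H, its RMSE, per-init losses."""

    H: np.ndarray
    rmse: float
    losses: np.ndarray        # final loss per init
    best_init: int
    loss_history: np.ndarray  # iterate losses of the winning init

    @property
    def rank(self) -> int:
        return self.H.shape[1]


@dataclass
class RankSelection:
    """Per-rank model-selection criteria over a rank sweep."""

    ranks: np.ndarray
    mean_rmse: np.ndarray
    best_rmse: np.ndarray
    dispersion: np.ndarray
    cophenetic: np.ndarray
    explained_variance: np.ndarray        # vs. mean(Y)
    explained_variance_zero: np.ndarray   # vs. 0
    results: dict[int, SymNMFResult] = field(default_factory=dict)

    def default_rank(self, min_ev: float = 0.8) -> int:
        """Smallest rank whose explained variance (vs. mean) reaches ``min_ev``."""
        ok = np.flatnonzero(self.explained_variance >= min_ev)
        if ok.size == 0:
            raise ValueError(f"no rank reaches explained variance {min_ev}")
        return int(self.ranks[ok[0]])


def _check_y(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != Y.shape[1]:
        raise ValueError("Y must be square")
    if not np.allclose(Y, Y.T, atol=1e-10):
        raise ValueError("Y must be symmetric")
    if Y.min() < 0:
        raise ValueError("Y must be nonnegative")
    return 0.5 * (Y + Y.T)


def _loss(Y: np.ndarray, H: np.ndarray) -> float:
    R = Y - H @ H.T
    return float(np.sum(R * R))


def _fit_once(
    Y: np.ndarray,
    H: np.ndarray,
    max_iter: int,
    tol: float,
    monotone_hook=None,
) -> tuple[np.ndarray, float, list[float]]:
    """Projected-gradient SymNMF with BB curvature scaling and Armijo search."""
    f = _loss(Y, H)
    history = [f]
    grad = 4.0 * ((H @ H.T) - Y) @ H
    alpha = 1.0 / max(np.abs(grad).max(), 1e-12)
    sigma, beta = 1e-4, 0.5
    H_prev, g_prev = None, None
    for _ in range(max_iter):
        if H_prev is not None:
            s = H - H_prev
            yv = grad - g_prev
            sy = float(np.sum(s * yv))
            if sy > 1e-16:
                alpha = float(np.sum(s * s)) / sy  # BB1 secant step
            alpha = float(np.clip(alpha, 1e-10, 1e6))
        accepted = False
        a = alpha
        for _bt in range(30):
            H_new = np.maximum(H - a * grad, 0.0)
            d = H_new - H
            f_new = _loss(Y, H_new)
            if f_new <= f + sigma * float(np.sum(grad * d)):
                accepted = True
                break
            a *= beta
        if not accepted or f_new > f:
            break  # no admissible decrease: stationary
        H_prev, g_prev = H, grad
        H, rel = H_new, (f - f_new) / max(f, 1e-300)
        f = f_new
        history.append(f)
        if monotone_hook is not None:
            monotone_hook(history)
        grad = 4.0 * ((H @ H.T) - Y) @ H
        if rel < tol:
            break
    return H, f, history


def symnmf(
    Y: np.ndarray,
    rank: int,
    n_inits: int = 250,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    return_all: bool = False,
):
    """Best-of-``n_inits`` SymNMF of Y at the given rank.

    Initial factor entries are uniform on [0, 1].  Returns the init with
    the lowest final loss; with ``return_all``, also the converged H of
    every init (used for consensus-based rank selection).
    """
    Y = _check_y(Y)
    if rank < 1 or rank > Y.shape[0]:
        raise ValueError("rank must be in [1, N]")
    if n_inits < 1:
        raise ValueError("need at least one initialization")
    N = Y.shape[0]
    best = None
    losses = np.empty(n_inits)
    all_H = []
    for i in range(n_inits):
        rng = derive_rng(seed, "symnmf-init", rank, i)
        H0 = rng.random((N, rank))
        H, f, hist = _fit_once(Y, H0, max_iter, tol)
        losses[i] = f
        if return_all:
            all_H.append(H)
        if best is None or f < best[1]:
            best = (H, f, hist, i)
    H, f, hist, idx = best
    rmse = float(np.sqrt(f / (N * N)))
    res = SymNMFResult(
        H=H, rmse=rmse, losses=losses, best_init=idx, loss_history=np.asarray(hist)
    )
    return (res, all_H) if return_all else res


def assign_clusters(H: np.ndarray, Y: np.ndarray | None = None) -> NetworkAssignment:
    """Region → argmax factor loading; ties to the lowest factor index.

    Assignment is computed on H exactly as returned (no column
    rescaling — rescaling would change the argmax).  Empty factors are
    dropped and labels compacted to 1..K.  A region whose loadings are
    all zero (possible in local optima when its allegiance row is nearly
    empty) is unassignable; if ``Y`` is supplied, such regions fall back
    to the factor their allegiance row aligns with most, argmax of (Y·H).
    """
    H = np.asarray(H, dtype=float)
    zero_rows = np.flatnonzero(H.max(axis=1) == 0)
    if zero_rows.size and Y is None:
        raise ValueError(f"unassignable regions (all-zero loadings): {zero_rows.tolist()}")
    raw = H.argmax(axis=1)  # argmax takes the first maximum: lowest index on ties
    if zero_rows.size:
        align = np.asarray(Y, dtype=float)[zero_rows] @ H
        if np.any(align.max(axis=1) <= 0):
            raise ValueError(
                f"unassignable regions (no allegiance alignment): {zero_rows.tolist()}"
            )
        raw[zero_rows] = align.argmax(axis=1)
    used = np.unique(raw)
    remap = {old: new + 1 for new, old in enumerate(used)}
    labels = np.array([remap[r] for r in raw])
    return NetworkAssignment(labels=labels, provenance="symnmf")


def _consensus(all_H: list[np.ndarray]) -> np.ndarray:
    N = all_H[0].shape[0]
    cbar = np.zeros((N, N))
    for H in all_H:
        lab = assign_clusters(H).labels
        cbar += lab[:, None] == lab[None, :]
    return cbar / len(all_H)


def _dispersion(cbar: np.ndarray) -> float:
    """ρ = (1/N²) ΣΣ 4 (c̄_ij − ½)²; 1 iff consensus entries are all 0/1."""
    return float(np.mean(4.0 * (cbar - 0.5) ** 2))


def _cophenetic(cbar: np.ndarray) -> float:
    """Correlation between average-linkage cophenetic distances and 1 − c̄."""
    d = squareform(1.0 - cbar, checks=False)
    if np.ptp(d) == 0:
        return 1.0  # perfectly consistent consensus
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    return float(c)


def rank_selection(
    Y: np.ndarray,
    ranks=range(2, 16),
    n_inits: int = 250,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> RankSelection:
    """Sweep candidate ranks and report all selection criteria per rank."""
    Y = _check_y(Y)
    N = Y.shape[0]
    ss_mean = float(np.sum((Y - Y.mean()) ** 2))
    ss_zero = float(np.sum(Y * Y))
    ranks = np.asarray(list(ranks), dtype=int)
    mean_rmse = np.empty(ranks.size)
    best_rmse = np.empty(ranks.size)
    disp = np.empty(ranks.size)
    coph = np.empty(ranks.size)
    ev_mean = np.empty(ranks.size)
    ev_zero = np.empty(ranks.size)
    results: dict[int, SymNMFResult] = {}
    for j, r in enumerate(ranks):
        res, all_H = symnmf(
            Y, int(r), n_inits=n_inits, seed=seed, max_iter=max_iter, tol=tol,
            return_all=True,
        )
        results[int(r)] = res
        mean_rmse[j] = float(np.mean(np.sqrt(res.losses / (N * N))))
        best_rmse[j] = res.rmse
        cbar = _consensus(all_H)
        disp[j] = _dispersion(cbar)
        coph[j] = _cophenetic(cbar)
        best_ss = float(res.losses[res.best_init])
        ev_mean[j] = 1.0 - best_ss / ss_mean if ss_mean > 0 else np.nan
        ev_zero[j] = 1.0 - best_ss / ss_zero
    return RankSelection(
        ranks=ranks,
        mean_rmse=mean_rmse,
        best_rmse=best_rmse,
        dispersion=disp,
        cophenetic=coph,
        explained_variance=ev_mean,
        explained_variance_zero=ev_zero,
        results=results,
    )
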