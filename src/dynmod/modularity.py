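"""Multilayer (multislice) modularity maximization.

The quality function scores a joint partition of all (region, window)
supra-nodes:

    Q = (1/2μ) Σ_{ijlr} [ (A_ijl − γ k_il k_jl / (2 m_l)) δ_lr
                          + δ_ij ω c_lr ] δ(g_il, g_jr)

with Newman–Girvan intra-layer null, resolution γ, inter-layer coupling
ω on temporally adjacent layers (c_lr = 1 iff |l−r| = 1), and 2μ the
total multilayer weight including couplings.  Partitions are found with
a generalized Louvain heuristic whose first-phase node sweep selects
among quality-increasing moves at random with probability proportional
to the increase, re-fed on itself until stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_rng

__all__ = [
    "QualityParams",
    "Partition",
    "PartitionEnsemble",
    "multilayer_quality",
    "supra_modularity_matrix",
    "genlouvain_partition",
    "partition_ensemble",
    "modularity_null_test",
]

_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class QualityParams:
    """Resolution (γ > 0) and inter-layer coupling (ω >= 0); defaults 1, 1."""

    gamma: float = 1.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass
class Partition:
    """L×N integer module labels g_il plus the quality Q they achieve."""

    labels: np.ndarray
    quality: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be L×N")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative integers")

    @property
    def n_layers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_regions(self) -> int:
        return self.labels.shape[1]


@dataclass
class PartitionEnsemble:
    """R independent clustering solutions for one multislice network."""

    partitions: list[Partition] = field(default_factory=list)

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def mean_quality(self) -> float:
        return float(np.mean([p.quality for p in self.partitions]))


def _layer_terms(layers: np.ndarray, gamma: float):
    """Per-layer modularity matrices A − γ kkᵀ/(2m) and total intra weight."""
    L = layers.shape[0]
    mats = np.empty_like(layers)
    two_mu_intra = 0.0
    for l in range(L):
        A = layers[l]
        k = A.sum(axis=1)
        two_m = k.sum()
        if two_m > 0:
            mats[l] = A - gamma * np.outer(k, k) / two_m
        else:
            mats[l] = A  # empty layer: only coupling terms contribute
        two_mu_intra += two_m
    return mats, two_mu_intra


def _two_mu(layers: np.ndarray, omega: float, coupling: np.ndarray | None = None) -> float:
    L, N = layers.shape[0], layers.shape[1]
    intra = float(sum(layers[l].sum() for l in range(L)))
    if coupling is None:
        inter = 2.0 * omega * N * (L - 1)
    else:
        inter = float(omega * coupling.sum())
    return intra + inter


def multilayer_quality(
    net, labels: np.ndarray, params: QualityParams = QualityParams()
) -> float:
    """Quality Q of an L×N labeling of a multislice network."""
    layers = np.asarray(net.layers, dtype=float)
    labels = np.asarray(labels, dtype=int)
    L, N = layers.shape[0], layers.shape[1]
    if labels.shape != (L, N):
        raise ValueError(f"labels shape {labels.shape} does not match network ({L}, {N})")
    two_mu = _two_mu(layers, params.omega)
    if two_mu == 0:
        raise ValueError("undefined Q: empty network with omega = 0")
    mats, _ = _layer_terms(layers, params.gamma)
    q = 0.0
    for l in range(L):
        same = labels[l][:, None] == labels[l][None, :]
        q += mats[l][same].sum()
    if params.omega > 0:
        for l in range(L - 1):
            q += 2.0 * params.omega * np.count_nonzero(labels[l] == labels[l + 1])
    return q / two_mu


def supra_modularity_matrix(net, params: QualityParams = QualityParams()):
    """Dense (L·N)×(L·N) supra matrix B with coupling, plus 2μ.

    Supra-node index s = l*N + i.  Q(labels) = Σ B_st δ(g_s, g_t) / 2μ.
    """
    layers = np.asarray(net.layers, dtype=float)
    L, N = layers.shape[0], layers.shape[1]
    S = L * N
    mats, _ = _layer_terms(layers, params.gamma)
    B = np.zeros((S, S))
    for l in range(L):
        B[l * N : (l + 1) * N, l * N : (l + 1) * N] = mats[l]
    if params.omega > 0:
        idx = np.arange(N)
        for l in range(L - 1):
            B[l * N + idx, (l + 1) * N + idx] = params.omega
            B[(l + 1) * N + idx, l * N + idx] = params.omega
    return B, _two_mu(layers, params.omega)


def _module_matrix(labels: np.ndarray, n_modules: int) -> np.ndarray:
    M = np.zeros((labels.size, n_modules))
    M[np.arange(labels.size), labels] = 1.0
    return M


def _sweep(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
           probabilistic: bool, max_sweeps: int) -> tuple[np.ndarray, bool]:
    """Phase-1 node sweep: move nodes between existing modules until no
    quality-increasing move remains.  Returns (labels, any_move_made).

    Maintains W = B·M (node-to-module link weights) incrementally: a move
    of node i from module a to c only touches columns a and c.
    """
    S = B.shape[0]
    _, labels = np.unique(labels, return_inverse=True)
    K = labels.max() + 1
    W = B @ _module_matrix(labels, K)
    diag = np.diag(B)
    improved_any = False
    for _ in range(max_sweeps):
        moved = False
        for i in rng.permutation(S):
            a = labels[i]
            gains = W[i] - (W[i, a] - diag[i])
            gains[a] = 0.0
            pos = np.flatnonzero(gains > _GAIN_TOL)
            if pos.size == 0:
                continue
            if probabilistic and pos.size > 1:
                g = gains[pos]
                cum = np.cumsum(g)
                c = int(pos[np.searchsorted(cum, rng.random() * cum[-1], side="right")])
            elif probabilistic:
                c = int(pos[0])
            else:
                c = int(pos[np.argmax(gains[pos])])
            labels[i] = c
            col = B[:, i]
            W[:, a] -= col
            W[:, c] += col
            moved = improved_any = True
        if not moved:
            return labels, improved_any
    raise RuntimeError(f"Louvain node sweep did not converge within {max_sweeps} sweeps")


def _louvain_pass(B: np.ndarray, init: np.ndarray, rng: np.random.Generator,
                  max_sweeps: int) -> np.ndarray:
    """One full Louvain run (probabilistic first phase, deterministic
    aggregation phases) starting from ``init`` labels on supra-nodes."""
    labels, _ = _sweep(B, init, rng, probabilistic=True, max_sweeps=max_sweeps)
    mapping = labels
    while True:
        uniq, compact = np.unique(mapping, return_inverse=True)
        K = len(uniq)
        M = _module_matrix(compact, K)
        B_agg = M.T @ B @ M
        agg_labels, improved = _sweep(
            B_agg, np.arange(K), rng, probabilistic=False, max_sweeps=max_sweeps
        )
        if not improved:
            return compact
        mapping = agg_labels[compact]


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules in order of first appearance (permutation-invariant form)."""
    flat = labels.ravel()
    _, first = np.unique(flat, return_index=True)
    order = flat[np.sort(first)]
    remap = {old: new for new, old in enumerate(order)}
    return np.vectorize(remap.get)(labels)


def genlouvain_partition(
    net,
    params: QualityParams = QualityParams(),
    seed: int | np.random.Generator = 0,
    max_outer: int = 100,
    max_sweeps: int = 1000,
) -> Partition:
    """Generalized Louvain on the L·N supra-node problem.

    The converged partition is re-fed as the initial condition until the
    output matches the input (up to module relabeling).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layers = np.asarray(net.layers, dtype=float)
    L, N = layers.shape[0], layers.shape[1]
    B, two_mu = supra_modularity_matrix(net, params)
    if two_mu == 0:
        raise ValueError("undefined Q: empty network with omega = 0")
    labels = np.arange(L * N)  # singleton start
    prev = None
    for _ in range(max_outer):
        labels = _louvain_pass(B, labels, rng, max_sweeps)
        cur = _canonical(labels.reshape(L, N))
        if prev is not None and np.array_equal(cur, prev):
            break
        prev = cur
        labels = cur.ravel()
    else:
        raise RuntimeError(f"generalized Louvain did not stabilize within {max_outer} outer iterations")
    q = multilayer_quality(net, prev, params)
    return Partition(labels=prev, quality=q)


def partition_ensemble(
    net,
    n_runs: int = 100,
    params: QualityParams = QualityParams(),
    seed: int = 0,
) -> PartitionEnsemble:
    """R independent seeded Louvain runs; subject-level Q is the ensemble mean."""
    parts = []
    for r in range(n_runs):
        rng = derive_rng(seed, "genlouvain", r)
        parts.append(genlouvain_partition(net, params, seed=rng))
    return PartitionEnsemble(partitions=parts)


def _null_network(net, kind: str, rng: np.random.Generator):
    """Draw one null multislice network (or permuted coupling) of the given family."""
    from .connectivity import MultilayerNetwork

    layers = net.layers.copy()
    L, N = layers.shape[0], layers.shape[1]
    if kind == "temporal":
        layers = layers[rng.permutation(L)]
        coupling_perms = None
    elif kind == "connectional":
        iu = np.triu_indices(N, k=1)
        for l in range(L):
            w = layers[l][iu]
            w = w[rng.permutation(w.size)]
            mat = np.zeros((N, N))
            mat[iu] = w
            layers[l] = mat + mat.T
        coupling_perms = None
    elif kind == "nodal":
        coupling_perms = [rng.permutation(N) for _ in range(L - 1)]
    else:
        raise ValueError(f"unknown null kind {kind!r}")
    null_net = MultilayerNetwork(
        layers=layers, window=net.window, band=net.band, threshold=net.threshold
    )
    return null_net, coupling_perms


def _quality_with_permuted_coupling(net, params, perms, n_runs, seed) -> float:
    """Mean Louvain Q when node i in layer l couples to perm_l(i) in layer l+1."""
    layers = np.asarray(net.layers, dtype=float)
    L, N = layers.shape[0], layers.shape[1]
    B, two_mu = supra_modularity_matrix(net, QualityParams(params.gamma, 0.0))
    two_mu += 2.0 * params.omega * N * (L - 1)
    idx = np.arange(N)
    for l in range(L - 1):
        B[l * N + idx, (l + 1) * N + perms[l]] += params.omega
        B[(l + 1) * N + perms[l], l * N + idx] += params.omega
    qs = []
    for r in range(n_runs):
        rng = derive_rng(seed, "nodal-null", r)
        labels = np.arange(L * N)
        prev = None
        for _ in range(100):
            labels = _louvain_pass(B, labels, rng, 1000)
            cur = _canonical(labels.reshape(L, N))
            if prev is not None and np.array_equal(cur, prev):
                break
            prev = cur
            labels = cur.ravel()
        flat = prev.ravel()
        M = _module_matrix(flat, flat.max() + 1)
        qs.append(float(np.einsum("sk,st,tk->", M, B, M)) / two_mu)
    return float(np.mean(qs))


def modularity_null_test(
    net,
    n_nulls: int = 100,
    null_kind: str = "connectional",
    params: QualityParams = QualityParams(),
    n_runs: int = 5,
    seed: int = 0,
) -> dict:
    """Permutation test of observed mean Q against a null-network family.

    p = (1 + #{null mean Q >= observed}) / (n_nulls + 1).
    """
    if n_nulls < 19:
        raise ValueError("n_nulls must be >= 19")
    obs = partition_ensemble(net, n_runs=n_runs, params=params, seed=seed).mean_quality
    rng = derive_rng(seed, "null-test", null_kind)
    null_qs = np.empty(n_nulls)
    for b in range(n_nulls):
        null_net, perms = _null_network(net, null_kind, rng)
        if perms is None:
            null_qs[b] = partition_ensemble(
                null_net, n_runs=n_runs, params=params, seed=int(rng.integers(2**31))
            ).mean_quality
        else:
            null_qs[b] = _quality_with_permuted_coupling(
                null_net, params, perms, n_runs, int(rng.integers(2**31))
            )
    p = (1.0 + np.count_nonzero(null_qs >= obs)) / (n_nulls + 1.0)
    return {"p": float(p), "observed_q": float(obs), "null_q": null_qs}
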