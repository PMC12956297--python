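"""Modularity of co-fluctuation patterns under a uniform null model.

Event patterns are similarity-like matrices, not sparse graphs, so the null
expectation of an edge weight is taken to be the mean weight over all node
pairs (a uniform null) rather than a degree-preserving null. The modularity
matrix is B = W - gamma * mean(W_offdiag) and

    Q = sum_{i<j, same module} B_ij / sum_{i<j} |W_ij|,

normalized by the total absolute weight so values are scale-invariant and
comparable across matrices. Partitions are found with a generalized Louvain
heuristic (greedy node moves + graph aggregation) seeded for repeatability,
and run-to-run variability is resolved by consensus clustering of the module
co-assignment matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nulls import SpinSet

__all__ = [
    "Partition",
    "modularity_uniform",
    "louvain_run",
    "consensus_partition",
    "frequency_weighted_Q",
    "module_system_composition",
]


@dataclass
class Partition:
    labels: np.ndarray  # node -> module id, contiguous from 1
    Q: float
    gamma: float = 1.0

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


def _check_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if not np.allclose(np.diag(W), 0.0):
        W = W.copy()
        np.fill_diagonal(W, 0.0)
    return W


def _uniform_B(W: np.ndarray, gamma: float) -> tuple[np.ndarray, float]:
    n = W.shape[0]
    offdiag_sum_abs = np.abs(W).sum() / 2.0
    if offdiag_sum_abs == 0:
        raise ValueError("all-zero W: modularity normalization undefined")
    wbar = W.sum() / (n * (n - 1))
    B = W - gamma * wbar
    np.fill_diagonal(B, 0.0)
    return B, offdiag_sum_abs


def modularity_uniform(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Q of a given partition under the uniform (mean-weight) null."""
    W = _check_matrix(W)
    labels = np.asarray(labels)
    B, norm = _uniform_B(W, gamma)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    return float(B[same].sum() / 2.0 / norm)


def _relabel(labels: np.ndarray) -> np.ndarray:
    _, out = np.unique(labels, return_inverse=True)
    return out


def _move_phase(B: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Greedy node moves on modularity matrix B until no move improves Q."""
    n = B.shape[0]
    labels = np.arange(n)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in rng.permutation(n):
            li = labels[i]
            w = np.bincount(labels, weights=B[i], minlength=n)
            w_own = w[li] - B[i, i]
            w[li] = w_own
            best = int(np.argmax(w))
            if w[best] > w_own + 1e-12:
                labels[i] = best
                moved = improved = True
            elif w_own < -1e-12 and w[best] <= 1e-12:
                counts = np.bincount(labels, minlength=n)
                counts[labels[i]] -= 1
                empty = np.flatnonzero(counts == 0)
                if empty.size:
                    labels[i] = int(empty[0])
                    moved = improved = True
    return _relabel(labels), improved


def louvain_run(W: np.ndarray, gamma: float = 1.0, seed: int | np.random.Generator = 0) -> Partition:
    """One seeded generalized-Louvain run on the uniform-null modularity matrix.

    Node-move passes alternate with graph aggregation until no move improves
    Q; the returned Q is never below the singleton-partition value 0.
    """
    W = _check_matrix(W)
    rng = np.random.default_rng(seed)
    B, _ = _uniform_B(W, gamma)
    node_map = np.arange(W.shape[0])
    B_cur = B
    prev_q_raw = -np.inf
    while True:
        comm, improved = _move_phase(B_cur, rng)
        node_map = comm[node_map]
        # raw (unnormalized) Q must never decrease across phases
        same = node_map[:, None] == node_map[None, :]
        np.fill_diagonal(same, False)
        q_raw = B[same].sum() / 2.0
        if q_raw < prev_q_raw - 1e-9:
            raise AssertionError("Louvain Q decreased across a phase")
        prev_q_raw = q_raw
        n_comm = comm.max() + 1
        if not improved or n_comm == B_cur.shape[0]:
            break
        onehot = np.eye(n_comm)[comm]
        B_cur = onehot.T @ B_cur @ onehot
    labels = _relabel(node_map) + 1
    return Partition(labels=labels, Q=modularity_uniform(W, labels, gamma), gamma=gamma)


def consensus_partition(
    W: np.ndarray,
    gamma: float = 1.0,
    n_runs: int = 100,
    tau: float | None = None,
    seed: int | np.random.Generator = 0,
    batch: int = 50,
    max_consensus_iter: int = 50,
) -> tuple[Partition, np.ndarray]:
    """Consensus over repeated Louvain runs via the co-assignment matrix.

    C_ij is the fraction of runs assigning i and j to the same module. The
    co-assignment matrix, thresholded at ``tau`` (default: the permutation
    null expectation implied by the runs' module sizes), is re-clustered
    iteratively until a verification batch of runs all agree.
    Returns (consensus partition of the original W, co-assignment matrix).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    W = _check_matrix(W)
    rng = np.random.default_rng(seed)
    n = W.shape[0]

    def run_batch(mat: np.ndarray, m_runs: int, uniform: bool) -> list[np.ndarray]:
        out = []
        for _ in range(m_runs):
            if uniform:
                p = louvain_run(mat, gamma=gamma, seed=rng)
            else:
                p = _louvain_on_B(mat, rng)
            out.append(p if isinstance(p, np.ndarray) else p.labels)
        return out

    def null_tau(run_labels: list[np.ndarray]) -> float:
        # expected co-assignment of label-permuted runs, from module sizes
        exp = []
        for lab in run_labels:
            sizes = np.bincount(_relabel(lab))
            exp.append(np.sum(sizes * (sizes - 1)) / (n * (n - 1)))
        return float(np.mean(exp))

    def raw_q(B: np.ndarray, lab: np.ndarray) -> float:
        same = lab[:, None] == lab[None, :]
        np.fill_diagonal(same, False)
        return float(B[same].sum())

    runs = run_batch(W, n_runs, uniform=True)
    C = _coassignment(runs)
    current = C
    cur_tau = null_tau(runs) if tau is None else tau
    for _ in range(max_consensus_iter):
        Bmat = current - cur_tau
        np.fill_diagonal(Bmat, 0.0)
        batch_runs = run_batch(Bmat, batch, uniform=False)
        # runs stuck in worse local optima do not veto convergence: agreement
        # is required among the best-scoring partitions only
        scores = np.array([raw_q(Bmat, lab) for lab in batch_runs])
        top = [lab for lab, s in zip(batch_runs, scores) if s >= scores.max() - 1e-9]
        if all(_same_partition(top[0], other) for other in top[1:]):
            labels = _relabel(top[0]) + 1
            return (
                Partition(labels=labels, Q=modularity_uniform(W, labels, gamma), gamma=gamma),
                C,
            )
        current = _coassignment(batch_runs)
        if tau is None:  # re-estimate the null level for the new matrix
            cur_tau = null_tau(batch_runs)
    raise RuntimeError("consensus clustering did not converge")


def _louvain_on_B(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Louvain phases directly on a pre-centered modularity matrix."""
    node_map = np.arange(B.shape[0])
    B_cur = B
    while True:
        comm, improved = _move_phase(B_cur, rng)
        node_map = comm[node_map]
        n_comm = comm.max() + 1
        if not improved or n_comm == B_cur.shape[0]:
            return node_map
        onehot = np.eye(n_comm)[comm]
        B_cur = onehot.T @ B_cur @ onehot


def _coassignment(runs: list[np.ndarray]) -> np.ndarray:
    n = len(runs[0])
    C = np.zeros((n, n))
    for lab in runs:
        C += lab[:, None] == lab[None, :]
    C /= len(runs)
    np.fill_diagonal(C, 1.0)
    return C


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    return np.array_equal(_relabel(a), _relabel(b))


def frequency_weighted_Q(q_per_cluster: np.ndarray, freq_per_cluster: np.ndarray) -> float:
    """Frequency-weighted modularity: sum_k f_k Q_k / sum_k f_k."""
    q = np.asarray(q_per_cluster, dtype=float)
    f = np.asarray(freq_per_cluster, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    if f.sum() == 0:
        raise ValueError("frequencies must not all be zero")
    return float(np.sum(f * q) / f.sum())


def module_system_composition(
    partition: Partition,
    system_labels,
    spins: SpinSet,
) -> pd.DataFrame:
    """Per-(module, system) proportion |module ∩ system| / |system| with a
    spin-test p-value: p = (1 + #{spin proportion >= observed}) / (1 + n_perm)."""
    labels = np.asarray(partition.labels)
    systems = np.asarray(system_labels)
    if len(labels) != len(systems):
        raise ValueError("partition and system labels must cover the same nodes")
    sys_names = sorted(set(systems.tolist()))
    records = []
    for m in np.unique(labels):
        in_mod = labels == m
        for s in sys_names:
            in_sys = systems == s
            obs = np.sum(in_mod & in_sys) / in_sys.sum()
            # spin the module assignment over nodes
            spun = in_mod[spins.permutations]  # n_perm x n_nodes
            null = spun[:, in_sys].sum(axis=1) / in_sys.sum()
            p = (1.0 + np.sum(null >= obs)) / (1.0 + spins.n_perm)
            records.append({"module": int(m), "system": s, "proportion": float(obs), "p": p})
    return pd.DataFrame(records)
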