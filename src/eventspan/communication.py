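"""Structural-connectome communication measures and event-pattern coupling.

A structural connectome (SC) is turned into a named ensemble of node x node
predictor matrices, each embodying a communication policy: pure geometry
(Euclidean distance), diffusion-like broadcasting (binary and weighted
communicability), routing (binary/weighted shortest-path length), and random
walks (mean first passage time, search information). Per node, the variance
in an event co-fluctuation pattern's connectivity profile explained by each
predictor's profile quantifies structure-function coupling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from .nulls import SpinSet, fdr_bh

__all__ = [
    "StructuralConnectome",
    "CommunicationEnsemble",
    "CouplingResult",
    "normalize_sc",
    "euclidean_distance",
    "communicability_binary",
    "communicability_weighted",
    "extended_measures",
    "nodal_r2",
    "coupling_matrix",
    "max_r2_per_node",
    "coupling_age_trend",
    "MEASURE_REGISTRY",
]

logger = logging.getLogger(__name__)


@dataclass
class StructuralConnectome:
    weights: np.ndarray  # symmetric, nonnegative, zero diagonal
    coords: np.ndarray | None = None  # node centers, mm
    volumes: np.ndarray | None = None  # mm^3

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.allclose(w, w.T):
            raise ValueError("SC weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("SC weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class CommunicationEnsemble:
    """Named predictor matrices plus their polarity (True: larger = easier)."""

    measures: dict[str, np.ndarray]
    polarity: dict[str, bool] = field(default_factory=dict)


@dataclass
class CouplingResult:
    r2: np.ndarray  # n_nodes x n_measures
    measure_names: list[str]

    @property
    def argmax_measure(self) -> np.ndarray:
        return np.argmax(self.r2, axis=1)  # ties -> first (name order)


def normalize_sc(
    streamline_counts: np.ndarray,
    volumes: np.ndarray,
    coords: np.ndarray | None = None,
) -> StructuralConnectome:
    """Normalize streamline counts by the geometric average of node volumes:
    w_ij = counts_ij / sqrt(vol_i * vol_j)."""
    counts = np.asarray(streamline_counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if np.any(volumes <= 0):
        raise ValueError("node volumes must be strictly positive")
    geo = np.sqrt(np.outer(volumes, volumes))
    return StructuralConnectome(weights=counts / geo, coords=coords, volumes=volumes)


def euclidean_distance(coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance between node centers (mm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be n_nodes x 3")
    return squareform(pdist(coords))


def communicability_binary(adjacency: np.ndarray) -> np.ndarray:
    """Binary communicability G = exp(A): the p-step walk count between each
    pair, weighted 1/p! so longer walks are penalized."""
    A = np.asarray(adjacency, dtype=float)
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not np.all(np.isin(A, (0.0, 1.0))):
        raise ValueError("adjacency must be binary")
    return expm(A)


def communicability_weighted(weights: np.ndarray) -> np.ndarray:
    """Weighted communicability G = exp(D^{-1/2} A D^{-1/2}), D = diag(strength)."""
    A = np.asarray(weights, dtype=float)
    if not np.allclose(A, A.T):
        raise ValueError("weights must be symmetric")
    strength = A.sum(axis=1)
    if np.any(strength <= 0):
        raise ValueError("isolated node (zero strength); weighted communicability undefined")
    dinv = 1.0 / np.sqrt(strength)
    return expm(dinv[:, None] * A * dinv[None, :])


def _require_connected(W: np.ndarray) -> None:
    n_comp, _ = connected_components(csr_matrix(W), directed=False)
    if n_comp > 1:
        raise ValueError("SC is disconnected; communication measures undefined")


def _shortest_paths(lengths: np.ndarray, return_predecessors: bool = False):
    return dijkstra(
        csr_matrix(lengths), directed=False, return_predecessors=return_predecessors
    )


def _length_inv(W: np.ndarray) -> np.ndarray:
    L = np.zeros_like(W)
    nz = W > 0
    L[nz] = 1.0 / W[nz]
    return L


def _length_log(W: np.ndarray) -> np.ndarray:
    L = np.zeros_like(W)
    nz = W > 0
    L[nz] = -np.log(W[nz] / W.max()) + 1e-12  # strictly positive lengths
    return L


def mean_first_passage_time(W: np.ndarray) -> np.ndarray:
    """MFPT of the unbiased random walk on W, via the fundamental matrix.

    M_ij = (Z_jj - Z_ij) / pi_j with Z = inv(I - P + 1 pi^T) and pi the
    stationary distribution (strength / total strength). Asymmetric.
    """
    strength = W.sum(axis=1)
    P = W / strength[:, None]
    pi = strength / strength.sum()
    n = W.shape[0]
    Z = np.linalg.inv(np.eye(n) - P + np.outer(np.ones(n), pi))
    M = (np.diag(Z)[None, :] - Z) / pi[None, :]
    np.fill_diagonal(M, 0.0)
    return M


def search_information(W: np.ndarray, lengths: np.ndarray | None = None) -> np.ndarray:
    """Bits needed for a random walker to follow the shortest path i -> j.

    S_ij = -log2 prod over shortest-path steps (u -> v) of W_uv / strength_u,
    with the path taken in the ``lengths`` transform (default 1/w). Asymmetric.
    """
    if lengths is None:
        lengths = _length_inv(W)
    strength = W.sum(axis=1)
    _, pred = _shortest_paths(lengths, return_predecessors=True)
    n = W.shape[0]
    S = np.zeros((n, n))
    logp = np.full((n, n), -np.inf)
    nz = W > 0
    logp[nz] = np.log2(W[nz] / strength[:, None].repeat(n, axis=1)[nz])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # walk the predecessor chain j -> i, accumulating step log-probs
            total = 0.0
            v = j
            while v != i:
                u = pred[i, v]
                total += logp[u, v]
                v = u
            S[i, j] = -total
    return S


MEASURE_REGISTRY = {
    "euclid": False,  # larger = harder
    "comm_bin": True,
    "comm_wei": True,
    "spl_inv": False,
    "spl_log": False,
    "mfpt": False,
    "si": False,
}


def extended_measures(
    sc: StructuralConnectome,
    measures: tuple[str, ...] = tuple(MEASURE_REGISTRY),
    symmetrize: bool = True,
) -> CommunicationEnsemble:
    """Build the core predictor ensemble from one connectome.

    Measures: ``euclid`` (geometry), ``comm_bin``/``comm_wei``
    (communicability of the binarized / strength-normalized SC),
    ``spl_inv``/``spl_log`` (weighted shortest-path lengths under 1/w and
    -log(w/w_max) transforms), ``mfpt`` (mean first passage time), ``si``
    (search information). MFPT and SI are intrinsically asymmetric and are
    symmetrized as (M + M^T)/2 when ``symmetrize`` (flagged in polarity map).
    """
    W = sc.weights
    _require_connected(W)
    out: dict[str, np.ndarray] = {}
    pol: dict[str, bool] = {}
    for name in measures:
        if name not in MEASURE_REGISTRY:
            raise ValueError(f"unknown measure {name!r}; registry: {sorted(MEASURE_REGISTRY)}")
        if name == "euclid":
            if sc.coords is None:
                raise ValueError("euclid measure requires node coordinates")
            M = euclidean_distance(sc.coords)
        elif name == "comm_bin":
            M = communicability_binary((W > 0).astype(float))
        elif name == "comm_wei":
            M = communicability_weighted(W)
        elif name == "spl_inv":
            M = _shortest_paths(_length_inv(W))
        elif name == "spl_log":
            M = _shortest_paths(_length_log(W))
        elif name == "mfpt":
            M = mean_first_passage_time(W)
            if symmetrize:
                M = (M + M.T) / 2.0
        elif name == "si":
            M = search_information(W)
            if symmetrize:
                M = (M + M.T) / 2.0
        if not np.all(np.isfinite(M)):
            raise ValueError(f"measure {name!r} produced non-finite entries")
        out[name] = M
        pol[name] = MEASURE_REGISTRY[name]
    return CommunicationEnsemble(measures=out, polarity=pol)


def nodal_r2(pattern: np.ndarray, predictor: np.ndarray, node: int) -> float:
    """Variance in a node's pattern profile explained by its predictor profile.

    Simple linear regression of the node's off-diagonal pattern row on its
    off-diagonal predictor row; R^2 = squared Pearson r (sign- and
    affine-invariant). NaN if the predictor row is constant.
    """
    n = pattern.shape[0]
    mask = np.arange(n) != node
    x = np.asarray(predictor)[node, mask]
    y = np.asarray(pattern)[node, mask]
    if np.std(x) == 0:
        logger.warning("constant predictor row for node %d; R^2 undefined", node)
        return np.nan
    if np.std(y) == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def coupling_matrix(pattern: np.ndarray, ensemble: CommunicationEnsemble) -> CouplingResult:
    """Per-node R^2 for every measure in the ensemble (nodes x measures)."""
    names = sorted(ensemble.measures)
    n = pattern.shape[0]
    r2 = np.empty((n, len(names)))
    for m, name in enumerate(names):
        pred = ensemble.measures[name]
        for i in range(n):
            r2[i, m] = nodal_r2(pattern, pred, i)
    return CouplingResult(r2=r2, measure_names=names)


def max_r2_per_node(result: CouplingResult) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Per-node maximum R^2, its measure, and the measure histogram.

    Ties break toward the first measure in (sorted) name order.
    """
    if result.r2.shape[1] < 1:
        raise ValueError("need at least one measure")
    arg = result.argmax_measure
    best = result.r2[np.arange(result.r2.shape[0]), arg]
    names = np.asarray(result.measure_names)[arg]
    hist = pd.Series(names).value_counts().reindex(result.measure_names, fill_value=0)
    return best, names, hist


def coupling_age_trend(
    nodal_r2_per_bin: np.ndarray,
    bin_centers: np.ndarray,
    system_labels,
    spins: SpinSet,
    nonevent_r2_per_bin: np.ndarray | None = None,
    q: float = 0.01,
) -> pd.DataFrame:
    """System-level age trend of structure-function coupling with spin nulls.

    ``nodal_r2_per_bin``: n_bins x n_nodes nodal R^2 maps. Per system, r is
    the Pearson correlation of the system-mean R^2 with the bin centers.
    A system is significant iff (a) the spin-null p (nodal maps spun before
    system averaging) survives BH at rate ``q`` AND (b) |r| exceeds the
    corresponding nonevent trend magnitude (skipped with a flag if no
    nonevent baseline is supplied).
    """
    R = np.asarray(nodal_r2_per_bin, dtype=float)
    bin_centers = np.asarray(bin_centers, dtype=float)
    if R.shape[0] < 3:
        raise ValueError("need at least 3 age bins")
    labels = np.asarray(system_labels)
    systems = sorted(set(labels.tolist()))

    def system_trend(maps: np.ndarray) -> np.ndarray:
        rs = np.empty(len(systems))
        for s, name in enumerate(systems):
            vals = maps[:, labels == name].mean(axis=1)
            rs[s] = np.corrcoef(vals, bin_centers)[0, 1] if np.std(vals) > 0 else 0.0
        return rs

    r_obs = system_trend(R)
    null_r = np.empty((spins.n_perm, len(systems)))
    for p in range(spins.n_perm):
        null_r[p] = system_trend(R[:, spins.permutations[p]])
    exc = np.sum(np.abs(null_r) >= np.abs(r_obs)[None, :], axis=0)
    pvals = (1.0 + exc) / (1.0 + spins.n_perm)
    p_adj, sig_spin = fdr_bh(pvals, q=q)

    if nonevent_r2_per_bin is not None:
        r_ne = system_trend(np.asarray(nonevent_r2_per_bin, dtype=float))
        stronger = np.abs(r_obs) > np.abs(r_ne)
    else:
        logger.warning("no nonevent baseline; magnitude criterion skipped")
        r_ne = np.full(len(systems), np.nan)
        stronger = np.ones(len(systems), dtype=bool)
    return pd.DataFrame(
        {
            "system": systems,
            "r": r_obs,
            "r_nonevent": r_ne,
            "p": pvals,
            "p_adj": p_adj,
            "significant": sig_spin & stronger,
        }
    )


def system_mean_r2(nodal_map: np.ndarray, system_labels) -> pd.Series:
    """Convenience: mean nodal value per system (block average of a map)."""
    labels = np.asarray(system_labels)
    systems = sorted(set(labels.tolist()))
    return pd.Series(
        {s: float(np.mean(nodal_map[labels == s])) for s in systems}
    )
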