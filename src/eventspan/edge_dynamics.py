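"""Edge time series, co-fluctuation amplitude, circular-shift nulls, and event detection.

The edge time series (ETS) decomposes the Pearson correlation between two
z-scored nodal signals into its framewise contributions: for nodes *i*, *j*

    e_ij(t) = z_i(t) * z_j(t),          FC_ij = 1/(T-1) * sum_t e_ij(t),

so static functional connectivity is exactly the time average of the ETS.
Frames whose global co-fluctuation amplitude (the root-sum-square of the ETS
column) significantly exceeds a circular-shift surrogate null are "events":
moments of brain-wide, high-amplitude co-activity that contribute
disproportionately to static FC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NodeTimeSeries",
    "EdgeTimeSeries",
    "AmplitudeSeries",
    "EventSet",
    "pair_index",
    "vector_to_matrix",
    "matrix_to_vector",
    "zscore_rows",
    "compute_ets",
    "static_fc",
    "amplitude",
    "amplitude_from_z",
    "circular_shift_null",
    "detect_events",
]


@dataclass
class NodeTimeSeries:
    """Per-subject node activity, nodes x frames.

    ``valid_frame_mask`` marks usable frames (the analogue of dropping
    high-motion frames in real data); masked frames are removed before
    z-scoring.
    """

    values: np.ndarray
    node_ids: list[str] | None = None
    zscored: bool = False
    valid_frame_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D nodes x frames array")
        if self.node_ids is None:
            self.node_ids = [f"node{i:03d}" for i in range(self.values.shape[0])]
        if self.valid_frame_mask is None:
            self.valid_frame_mask = np.ones(self.values.shape[1], dtype=bool)
        self.valid_frame_mask = np.asarray(self.valid_frame_mask, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EdgeTimeSeries:
    """Co-fluctuation time series, node-pairs x frames.

    Rows follow the canonical 0-based row-major upper-triangle enumeration
    (i < j) returned by :func:`pair_index`.
    """

    values: np.ndarray
    n_nodes: int

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class AmplitudeSeries:
    """Per-frame global co-fluctuation amplitude (nonnegative)."""

    values: np.ndarray
    mode: str = "root_sum_square"


@dataclass
class EventSet:
    """Detected event frames with their amplitudes and the null summary."""

    frame_indices: np.ndarray
    amplitudes: np.ndarray
    threshold: float
    alpha: float
    null_samples: np.ndarray = field(repr=False, default=None)

    @property
    def n_events(self) -> int:
        return len(self.frame_indices)


def pair_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (i, j) arrays for the row-major upper triangle, i < j, 0-based."""
    return np.triu_indices(n_nodes, k=1)


def matrix_to_vector(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle vectorization in the canonical pair order."""
    mat = np.asarray(mat)
    iu = pair_index(mat.shape[0])
    return mat[iu]


def vector_to_matrix(vec: np.ndarray, n_nodes: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`matrix_to_vector`; fills a symmetric matrix."""
    vec = np.asarray(vec)
    iu = pair_index(n_nodes)
    if len(vec) != len(iu[0]):
        raise ValueError(f"vector length {len(vec)} != n_nodes*(n_nodes-1)/2 = {len(iu[0])}")
    out = np.full((n_nodes, n_nodes), float(diagonal))
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def zscore_rows(ts: NodeTimeSeries) -> NodeTimeSeries:
    """Z-score each node's series over valid frames (sample SD, T-1 denominator).

    Raises ``ValueError`` naming the offending node if any row is constant.
    """
    vals = ts.values[:, ts.valid_frame_mask]
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 valid frames to z-score")
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise ValueError(f"constant time series for node {ts.node_ids[bad[0]]!r} (index {bad[0]})")
    z = (vals - mu) / sd
    return NodeTimeSeries(
        values=z,
        node_ids=list(ts.node_ids),
        zscored=True,
        valid_frame_mask=np.ones(z.shape[1], dtype=bool),
    )


def compute_ets(z: NodeTimeSeries) -> EdgeTimeSeries:
    """Edge time series: e_ij(t) = z_i(t) * z_j(t) for every pair i < j."""
    if not z.zscored:
        raise ValueError("compute_ets requires z-scored input (call zscore_rows first)")
    iu, ju = pair_index(z.n_nodes)
    return EdgeTimeSeries(values=z.values[iu] * z.values[ju], n_nodes=z.n_nodes)


def static_fc(ts: NodeTimeSeries) -> np.ndarray:
    """Static functional connectivity: Pearson correlation matrix of nodes.

    Equals the time average of the edge time series scaled by 1/(T-1).
    """
    z = ts if ts.zscored else zscore_rows(ts)
    T = z.n_frames
    fc = (z.values @ z.values.T) / (T - 1)
    np.fill_diagonal(fc, 1.0)
    return np.clip(fc, -1.0, 1.0)


def amplitude(ets: EdgeTimeSeries, mode: str = "root_sum_square") -> AmplitudeSeries:
    """Global co-fluctuation amplitude per frame.

    ``root_sum_square`` (default): sqrt(sum over pairs of e(t)^2).
    ``root_mean_square``: the same divided by sqrt(n_pairs). The two differ
    by a constant, so frame rankings and quantile-based event sets coincide.
    """
    if mode not in ("root_sum_square", "root_mean_square"):
        raise ValueError(f"unknown amplitude mode {mode!r}")
    ss = np.einsum("pt,pt->t", ets.values, ets.values)
    if mode == "root_mean_square":
        ss = ss / ets.n_pairs
    return AmplitudeSeries(values=np.sqrt(ss), mode=mode)


def amplitude_from_z(z: np.ndarray, mode: str = "root_sum_square") -> np.ndarray:
    # O(N) per frame identity: 2*sum_{i<j}(z_i z_j)^2 = (sum z^2)^2 - sum z^4
    s2 = np.einsum("nt,nt->t", z, z)
    s4 = np.einsum("nt,nt,nt,nt->t", z, z, z, z)
    ss = np.maximum(s2 * s2 - s4, 0.0) / 2.0
    if mode == "root_mean_square":
        n = z.shape[0]
        ss = ss / (n * (n - 1) / 2)
    return np.sqrt(ss)


def circular_shift_null(
    ts: NodeTimeSeries,
    n_null: int,
    seed: int | np.random.Generator,
    mode: str = "root_sum_square",
) -> np.ndarray:
    """Null co-fluctuation amplitudes from circularly shifted surrogates.

    Each realization independently rotates every node's series by a uniform
    random offset in [1, T-1], re-z-scores, and recomputes the amplitude.
    The rotation is a permutation of each row, so every marginal moment of
    every node is preserved exactly while inter-node alignment is destroyed.

    Returns an (n_null, n_frames) array of null amplitude samples.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    z0 = ts if ts.zscored else zscore_rows(ts)
    x = z0.values
    n, T = x.shape
    out = np.empty((n_null, T))
    cols = np.arange(T)
    for k in range(n_null):
        offs = rng.integers(1, T, size=n)
        idx = (cols[None, :] - offs[:, None]) % T  # row i shifted right by offs[i]
        shifted = np.take_along_axis(x, idx, axis=1)
        out[k] = amplitude_from_z(shifted, mode=mode)
    return out


def detect_events(
    amp: AmplitudeSeries,
    null_samples: np.ndarray,
    alpha: float = 0.05,
    mode: str = "frame",
) -> EventSet:
    """Flag frames whose amplitude significantly exceeds the surrogate null.

    ``frame`` mode thresholds at the (1 - alpha) quantile of the pooled null
    amplitudes (per-frame error rate alpha; on null data it flags an alpha
    fraction of frames). ``peak`` mode additionally keeps only the
    maximum-amplitude frame of each contiguous supra-threshold segment.
    ``max`` mode controls the familywise rate across the whole run: the
    threshold is the (1 - alpha) quantile of each null realization's maximum
    amplitude (requires 2-D null_samples, one row per realization), which is
    the selectivity regime in which events occupy well under 1% of frames.
    """
    null_samples = np.asarray(null_samples, dtype=float)
    if null_samples.size == 0:
        raise ValueError("null_samples must be nonempty")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if mode not in ("frame", "peak", "max"):
        raise ValueError(f"unknown detection mode {mode!r}")
    if mode == "max":
        if null_samples.ndim != 2:
            raise ValueError("max mode needs per-realization null rows (2-D array)")
        thr = float(np.quantile(null_samples.max(axis=1), 1.0 - alpha))
    else:
        thr = float(np.quantile(null_samples, 1.0 - alpha))
    null_samples = null_samples.ravel()
    above = amp.values > thr
    idx = np.flatnonzero(above)
    if mode == "peak" and idx.size:  # keep each segment's argmax
        keep = []
        seg_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                seg = np.arange(seg_start, prev + 1)
                keep.append(seg[np.argmax(amp.values[seg])])
                seg_start = i
            prev = i
        seg = np.arange(seg_start, prev + 1)
        keep.append(seg[np.argmax(amp.values[seg])])
        idx = np.asarray(keep, dtype=int)
    return EventSet(
        frame_indices=idx,
        amplitudes=amp.values[idx],
        threshold=thr,
        alpha=alpha,
        null_samples=null_samples,
    )
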