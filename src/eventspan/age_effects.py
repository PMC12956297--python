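"""Age trends of event co-fluctuation patterns.

Group-mean pattern matrices per age bin, difference matrices against the
youngest bin, PCA of pattern topographies, system-block averaging, and
element-wise age correlations tested against an age-randomized permutation
null with Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nulls import fdr_bh

__all__ = [
    "SystemMatrix",
    "bin_ages",
    "group_mean_pattern",
    "difference_to_youngest",
    "pc1_scores",
    "system_block_average",
    "age_trend_with_null",
]

logger = logging.getLogger(__name__)


@dataclass
class SystemMatrix:
    """System-by-system mean co-fluctuation; entry (a, b) averages the edges
    with one endpoint in system a and the other in b (diagonal: within-system
    i < j pairs, excluding self-connections)."""

    values: np.ndarray
    system_names: list[str]


def bin_ages(ages, bin_edges=None, bin_width: float = 10.0, age_min: float = 6.0) -> np.ndarray:
    """Assign ages to half-open [low, high) bins.

    Either explicit ``bin_edges`` (length n_bins+1) or uniform bins of
    ``bin_width`` starting at ``age_min``. An age on an internal edge falls in
    the upper bin; an age outside every bin raises.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        return np.empty(0, dtype=int)
    if bin_edges is None:
        n_bins = int((ages.max() - age_min) // bin_width) + 1
        bin_edges = age_min + bin_width * np.arange(n_bins + 1)
    bin_edges = np.asarray(bin_edges, dtype=float)
    out = np.searchsorted(bin_edges, ages, side="right") - 1
    bad = (out < 0) | (out >= len(bin_edges) - 1) | (ages < bin_edges[0]) | (ages >= bin_edges[-1])
    if np.any(bad):
        raise ValueError(f"ages outside bin span: {ages[bad][:5]}")
    return out.astype(int)


def group_mean_pattern(
    event_matrices: np.ndarray,
    bin_assignment: np.ndarray,
    cluster_labels: np.ndarray,
) -> dict[tuple[int, int], np.ndarray]:
    """Arithmetic mean event matrix per (age bin, cluster) cell.

    ``event_matrices`` is n_events x n x n (or n_events x n_pairs); empty
    cells are omitted with a warning.
    """
    event_matrices = np.asarray(event_matrices, dtype=float)
    bin_assignment = np.asarray(bin_assignment)
    cluster_labels = np.asarray(cluster_labels)
    out: dict[tuple[int, int], np.ndarray] = {}
    for b in np.unique(bin_assignment):
        for k in np.unique(cluster_labels):
            sel = (bin_assignment == b) & (cluster_labels == k)
            if not np.any(sel):
                logger.warning("empty cell (bin=%s, cluster=%s); omitted", b, k)
                continue
            out[(int(b), int(k))] = event_matrices[sel].mean(axis=0)
    return out


def difference_to_youngest(
    group_means: dict[tuple[int, int], np.ndarray]
) -> dict[tuple[int, int], np.ndarray]:
    """Delta_b = mean_b - mean_youngest, per cluster (youngest delta is 0)."""
    bins = sorted({b for b, _ in group_means})
    if not bins:
        return {}
    youngest = bins[0]
    out = {}
    for (b, k), m in group_means.items():
        if (youngest, k) not in group_means:
            raise ValueError(f"youngest bin missing for cluster {k}")
        out[(b, k)] = m - group_means[(youngest, k)]
    return out


def pc1_scores(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading principal component of a symmetric pattern matrix.

    The diagonal is zeroed, columns are centered, and standard column PCA is
    applied: scores are the leading right singular vector (sign fixed so the
    maximum-|score| entry is positive) and the variance-explained fraction is
    lambda_1^2 / sum lambda^2 of the column covariance spectrum.
    """
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    work = mat.copy()
    np.fill_diagonal(work, 0.0)
    if np.allclose(work, 0.0):
        raise ValueError("degenerate input: zero off-diagonal pattern")
    centered = work - work.mean(axis=0, keepdims=True)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    scores = vt[0]
    if scores[np.argmax(np.abs(scores))] < 0:
        scores = -scores
    var_explained = float(svals[0] ** 2 / np.sum(svals**2))
    return scores, var_explained


def system_block_average(mat: np.ndarray, system_labels) -> SystemMatrix:
    """Average edges within/between systems, excluding the diagonal.

    A within-system block for a singleton system has no i < j pair; its entry
    is recorded as NaN (missing).
    """
    mat = np.asarray(mat, dtype=float)
    labels = np.asarray(system_labels)
    systems = sorted(set(labels.tolist()))
    S = len(systems)
    out = np.full((S, S), np.nan)
    offdiag = ~np.eye(mat.shape[0], dtype=bool)
    for a, sa in enumerate(systems):
        ia = labels == sa
        for b in range(a, S):
            ib = labels == systems[b]
            block_mask = np.outer(ia, ib) & offdiag
            if a == b and ia.sum() < 2:
                logger.warning("singleton system %s: within-block mean undefined", sa)
                continue
            out[a, b] = out[b, a] = mat[block_mask].mean()
    return SystemMatrix(values=out, system_names=[str(s) for s in systems])


def expand_system_matrix(sysmat: SystemMatrix, system_labels) -> np.ndarray:
    """Broadcast a system matrix back to node space (diagonal zeroed)."""
    labels = np.asarray(system_labels)
    idx = np.array([sysmat.system_names.index(str(s)) for s in labels])
    full = sysmat.values[np.ix_(idx, idx)]
    np.fill_diagonal(full, 0.0)
    return full


def age_trend_with_null(
    values: np.ndarray,
    ages: np.ndarray,
    n_perm: int = 5000,
    q: float = 0.01,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Element-wise Pearson age correlations against an age-randomized null.

    ``values`` is n_units x n_elements (units = age bins with bin-center ages,
    or subjects with subject ages). Per element: observed r; two-sided
    permutation p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm) with ages
    shuffled across units; BH adjustment at rate ``q`` over all elements.
    Returns a DataFrame with columns (element, r, p, p_adj, significant).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ages = np.asarray(ages, dtype=float)
    if values.shape[0] != ages.shape[0]:
        raise ValueError("values rows must match ages length")
    if ages.size < 3:
        raise ValueError("need at least 3 age points")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable p-value resolution")
    rng = np.random.default_rng(seed)

    ok = ~np.any(np.isnan(values), axis=0)

    def _corr_with(age_vec: np.ndarray) -> np.ndarray:
        a = (age_vec - age_vec.mean()) / age_vec.std()
        v = values[:, ok]
        vc = v - v.mean(axis=0)
        sd = vc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a @ vc) / (len(a) * np.where(sd == 0, np.inf, sd))
        return r  # zero-variance elements get r = 0 (and p ~ 1 downstream)

    r_obs = _corr_with(ages)
    null_r = np.empty((n_perm, ok.sum()))
    for p in range(n_perm):
        null_r[p] = _corr_with(rng.permutation(ages))
    exc = np.sum(np.abs(null_r) >= np.abs(r_obs)[None, :], axis=0)
    pvals = (1.0 + exc) / (1.0 + n_perm)
    finite = ~np.isnan(pvals)
    p_adj = np.full_like(pvals, np.nan)
    sig = np.zeros_like(pvals, dtype=bool)
    if finite.any():
        p_adj[finite], sig[finite] = fdr_bh(pvals[finite], q=q)

    full_r = np.full(values.shape[1], np.nan)
    full_p = np.full(values.shape[1], np.nan)
    full_padj = np.full(values.shape[1], np.nan)
    full_sig = np.zeros(values.shape[1], dtype=bool)
    full_r[ok], full_p[ok], full_padj[ok], full_sig[ok] = r_obs, pvals, p_adj, sig
    return pd.DataFrame(
        {
            "element": np.arange(values.shape[1]),
            "r": full_r,
            "p": full_p,
            "p_adj": full_padj,
            "significant": full_sig,
        }
    )
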