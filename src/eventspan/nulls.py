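"""Shared permutation machinery: spherical spin tests, permutation p-values, FDR.

The spin test builds spatially constrained permutations of nodal maps: node
coordinates on a sphere are rotated by a uniform random 3-D rotation and each
node is mapped to its nearest rotated neighbour, preserving the spatial
autocorrelation of the map while shuffling its alignment with any other map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

__all__ = ["SpinSet", "spin_permutations", "permutation_pvalue", "fdr_bh"]


@dataclass
class SpinSet:
    """A batch of spatially constrained node permutations (each a bijection)."""

    permutations: np.ndarray  # (n_perm, n_nodes) int
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.permutations.shape[0]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-corrected to a uniform proper rotation
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _nearest_bijection(coords: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Greedy bijection original -> rotated by ascending assignment distance."""
    d = cdist(coords, rotated)
    n = d.shape[0]
    order = np.argsort(d, axis=None)
    perm = np.full(n, -1, dtype=int)
    used_src = np.zeros(n, dtype=bool)
    used_dst = np.zeros(n, dtype=bool)
    assigned = 0
    for flat in order:
        i, j = divmod(int(flat), n)
        if used_src[i] or used_dst[j]:
            continue
        perm[i] = j
        used_src[i] = used_dst[j] = True
        assigned += 1
        if assigned == n:
            break
    return perm


def spin_permutations(coords: np.ndarray, n_perm: int, seed: int | np.random.Generator) -> SpinSet:
    """Random-rotation spin permutations for nodes on a common sphere.

    Requires the coordinates to lie approximately on one sphere about their
    centroid (radial SD / mean < 0.05). Each permutation row is a bijection.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be n_nodes x 3")
    centered = coords - coords.mean(axis=0)
    radii = np.linalg.norm(centered, axis=1)
    if radii.mean() == 0 or radii.std() / radii.mean() >= 0.05:
        raise ValueError("coords are not approximately on a common sphere")
    rank = np.linalg.matrix_rank(centered)
    if rank < 2:
        raise ValueError("degenerate (collinear) coordinates")
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, coords.shape[0]), dtype=int)
    for k in range(n_perm):
        rot = _random_rotation(rng)
        perms[k] = _nearest_bijection(centered, centered @ rot.T)
    return SpinSet(permutations=perms, seed=None if isinstance(seed, np.random.Generator) else seed)


def permutation_pvalue(observed: float, null_values: np.ndarray, sided: str = "two") -> float:
    """Permutation p with the +1 correction: p = (1 + exceedances) / (1 + n).

    ``sided``: "two" counts |null| >= |observed|, "greater" counts
    null >= observed, "less" counts null <= observed. Never returns 0.
    """
    null_values = np.ravel(np.asarray(null_values, dtype=float))
    n = null_values.size
    if n < 100:
        raise ValueError(f"need >= 100 null values for a usable resolution, got {n}")
    if sided == "two":
        exc = np.sum(np.abs(null_values) >= abs(observed))
    elif sided == "greater":
        exc = np.sum(null_values >= observed)
    elif sided == "less":
        exc = np.sum(null_values <= observed)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(1 + exc) / float(1 + n)


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR. Returns (adjusted p, rejection mask)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return p_adj.reshape(pvals.shape), reject.reshape(pvals.shape)
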