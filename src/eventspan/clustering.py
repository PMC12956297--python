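"""Clustering of pooled event frames into recurring co-fluctuation patterns.

Event frames (edge-vector columns of the ETS at detected event times) from an
age-balanced subject sample are pooled and partitioned with Lloyd-style
k-means under a similarity metric — Pearson correlation or Lin's concordance
correlation coefficient (CCC). The CCC penalizes scale and mean differences
as well as decorrelation, so it can separate patterns that differ only in
magnitude. Because k-means labels are arbitrary, models from repeated runs
are aligned by solving the linear assignment problem that minimizes total
centroid dissimilarity (1 - correlation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_rel

from .edge_dynamics import matrix_to_vector

__all__ = [
    "FrameBank",
    "ClusterModel",
    "sample_subjects",
    "subsample_frames",
    "lins_ccc",
    "kmeans_fit",
    "align_models",
    "similarity_curve",
    "cluster_descriptives",
    "relative_frequency",
]

logger = logging.getLogger(__name__)


@dataclass
class FrameBank:
    """Pooled event frames: n_events x n_pairs edge vectors with metadata."""

    frames: np.ndarray
    subject_ids: np.ndarray
    age_bin_ids: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        n = self.frames.shape[0]
        for name in ("subject_ids", "age_bin_ids", "frame_indices"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_frames {n}")
            setattr(self, name, arr)

    @property
    def n_events(self) -> int:
        return self.frames.shape[0]


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray  # K x n_pairs
    labels: np.ndarray  # per-frame assignment in [1..K]
    metric: str
    mean_within_similarity: np.ndarray  # per cluster
    objective: float = np.nan  # total within-cluster similarity


def sample_subjects(
    cohort: pd.DataFrame, n_per_group: int, seed: int | np.random.Generator
) -> list[str]:
    """Draw ``n_per_group`` subjects per age bin, with replacement.

    ``cohort`` needs columns ``subject`` and ``age_bin``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for b in sorted(cohort["age_bin"].unique()):
        members = cohort.loc[cohort["age_bin"] == b, "subject"].to_numpy()
        if len(members) == 0:
            raise ValueError(f"age bin {b} is empty")
        out.extend(rng.choice(members, size=n_per_group, replace=True).tolist())
    return out


def subsample_frames(
    events_per_subject: dict[str, np.ndarray],
    k: int,
    seed: int | np.random.Generator,
    age_bins: dict[str, int] | None = None,
    frame_indices: dict[str, np.ndarray] | None = None,
) -> FrameBank:
    """Keep at most ``k`` event frames per subject (uniform, without replacement).

    ``events_per_subject`` maps subject id -> (n_events x n_pairs) edge-vector
    array. Subjects with zero events are skipped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    rows, sids, bins, fidx = [], [], [], []
    for sid, frames in events_per_subject.items():
        frames = np.atleast_2d(np.asarray(frames, dtype=float))
        n = frames.shape[0]
        if n == 0 or frames.size == 0:
            logger.warning("subject %s has no events; skipped", sid)
            continue
        take = np.sort(rng.choice(n, size=min(k, n), replace=False))
        rows.append(frames[take])
        sids.extend([sid] * len(take))
        bins.extend([age_bins.get(sid, -1) if age_bins else -1] * len(take))
        if frame_indices is not None and sid in frame_indices:
            fidx.extend(np.asarray(frame_indices[sid])[take].tolist())
        else:
            fidx.extend(take.tolist())
    if not rows:
        raise ValueError("no subject contributed any event frames")
    return FrameBank(
        frames=np.vstack(rows),
        subject_ids=np.asarray(sids),
        age_bin_ids=np.asarray(bins),
        frame_indices=np.asarray(fidx),
    )


def lins_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population 1/n moments).

    rho_c = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2).
    Satisfies |rho_c| <= |pearson r|, with equality iff the two vectors have
    equal means and variances.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("vectors must have length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments
    if vx == 0 or vy == 0:
        raise ValueError("constant vector has undefined concordance")
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


def _similarity_to_centroids(frames: np.ndarray, centroids: np.ndarray, metric: str) -> np.ndarray:
    """(n_frames x K) similarity matrix under the chosen metric."""
    fm = frames.mean(axis=1, keepdims=True)
    cm = centroids.mean(axis=1, keepdims=True)
    fc = frames - fm
    cc = centroids - cm
    n = frames.shape[1]
    cov = fc @ cc.T / n
    fv = np.einsum("ij,ij->i", fc, fc) / n
    cv = np.einsum("ij,ij->i", cc, cc) / n
    if metric == "pearson":
        denom = np.sqrt(np.outer(fv, cv))
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = cov / denom
        return np.nan_to_num(sim)
    if metric == "lins_ccc":
        denom = fv[:, None] + cv[None, :] + (fm - cm.T) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = 2.0 * cov / denom
        return np.nan_to_num(sim)
    raise ValueError(f"unknown metric {metric!r}")


def kmeans_fit(
    bank: FrameBank,
    K: int,
    metric: str = "pearson",
    n_restarts: int = 10,
    max_iter: int = 100,
    seed: int | np.random.Generator = 0,
) -> ClusterModel:
    """Similarity k-means: assign to the most similar centroid, recompute means.

    Empty clusters are reseeded with the frame least similar to its own
    centroid; the best of ``n_restarts`` by total within-cluster similarity
    is returned. Argmax ties break toward the lowest cluster index.
    """
    X = bank.frames
    n = X.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of frames ({n})")
    rng = np.random.default_rng(seed)
    best: ClusterModel | None = None
    for _ in range(n_restarts):
        centroids = X[rng.choice(n, size=K, replace=False)].copy()
        labels = np.full(n, -1, dtype=int)
        for _ in range(max_iter):
            sim = _similarity_to_centroids(X, centroids, metric)
            new_labels = np.argmax(sim, axis=1)  # ties -> lowest index
            # empty-cluster repair: reseed with the frame farthest from its centroid
            moved: set[int] = set()
            for k in range(K):
                if not np.any(new_labels == k):
                    own = sim[np.arange(n), new_labels].astype(float)
                    if moved:
                        own[list(moved)] = np.inf  # one frame per empty cluster
                    worst = int(np.argmin(own))
                    new_labels[worst] = k
                    moved.add(worst)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for k in range(K):
                members = labels == k
                if members.any():
                    centroids[k] = X[members].mean(axis=0)
        sim = _similarity_to_centroids(X, centroids, metric)
        objective = float(sim[np.arange(n), labels].sum())
        if best is None or objective > best.objective:
            within = np.array(
                [
                    _mean_pairwise_similarity(X[labels == k], metric)
                    for k in range(K)
                ]
            )
            best = ClusterModel(
                K=K,
                centroids=centroids.copy(),
                labels=labels + 1,
                metric=metric,
                mean_within_similarity=within,
                objective=objective,
            )
    return best


def _mean_pairwise_similarity(frames: np.ndarray, metric: str) -> float:
    """Mean pairwise similarity among frames; 1.0 for a single-frame cluster."""
    m = frames.shape[0]
    if m < 2:
        return 1.0
    sim = _similarity_to_centroids(frames, frames, metric)
    iu = np.triu_indices(m, k=1)
    return float(sim[iu].mean())


def _centroid_cost(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise dissimilarity 1 - corr between two centroid sets."""
    return 1.0 - _similarity_to_centroids(a, b, "pearson")


def align_models(models: list[ClusterModel]) -> tuple[list[ClusterModel], np.ndarray]:
    """Align cluster labels across repeated k-means runs.

    The run with the highest objective is the reference; every other model's
    clusters are permuted by the optimal assignment minimizing total centroid
    dissimilarity (1 - correlation). Returns (aligned models, reference
    centroids).
    """
    Ks = {m.K for m in models}
    if len(Ks) != 1:
        raise ValueError(f"models have mismatched K: {sorted(Ks)}")
    K = Ks.pop()
    ref = max(models, key=lambda m: m.objective)
    aligned = []
    for m in models:
        cost = _centroid_cost(m.centroids, ref.centroids)
        rows, cols = linear_sum_assignment(cost)
        # cluster k of m becomes cluster cols[k] of the reference frame
        perm = np.empty(K, dtype=int)
        perm[rows] = cols
        new_centroids = np.empty_like(m.centroids)
        new_within = np.empty_like(m.mean_within_similarity)
        new_centroids[perm] = m.centroids
        new_within[perm] = m.mean_within_similarity
        aligned.append(
            ClusterModel(
                K=K,
                centroids=new_centroids,
                labels=perm[m.labels - 1] + 1,
                metric=m.metric,
                mean_within_similarity=new_within,
                objective=m.objective,
            )
        )
    return aligned, ref.centroids.copy()


def similarity_curve(
    models_per_K: dict[int, list[ClusterModel]]
) -> pd.DataFrame:
    """Mean matched-centroid similarity across aligned run pairs, per K.

    The K at which repeated clustering is most reproducible is the selected
    number of patterns.
    """
    records = []
    for K, models in sorted(models_per_K.items()):
        if len(models) < 2:
            raise ValueError(f"need >= 2 repetitions at K={K}")
        aligned, _ = align_models(models)
        sims = []
        for i in range(len(aligned)):
            for j in range(i + 1, len(aligned)):
                s = _similarity_to_centroids(
                    aligned[i].centroids, aligned[j].centroids, "pearson"
                )
                sims.append(np.diag(s).mean())
        records.append({"K": K, "mean_similarity": float(np.mean(sims))})
    return pd.DataFrame(records)


def cluster_descriptives(
    model: ClusterModel,
    bank: FrameBank,
    fc_per_subject: dict[str, np.ndarray],
    nonevent_mean_per_subject: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-subject similarity of each event class (and nonevents) to static FC.

    Similarity is the Pearson correlation of upper-triangle vectors between
    the subject's mean class pattern and the subject's static FC. Rows:
    (subject, class, similarity_to_fc, within_similarity).
    """
    records = []
    for sid, fc in fc_per_subject.items():
        fc_vec = matrix_to_vector(fc) if fc.ndim == 2 else np.asarray(fc)
        mask = bank.subject_ids == sid
        for k in range(1, model.K + 1):
            sel = mask & (model.labels == k)
            if not np.any(sel):
                logger.warning("subject %s has no frames in cluster %d", sid, k)
                continue
            frames = bank.frames[sel]
            mean_pat = frames.mean(axis=0)
            records.append(
                {
                    "subject": sid,
                    "class": f"C{k}",
                    "similarity_to_fc": float(np.corrcoef(mean_pat, fc_vec)[0, 1]),
                    "within_similarity": _mean_pairwise_similarity(frames, model.metric),
                }
            )
        if nonevent_mean_per_subject and sid in nonevent_mean_per_subject:
            ne = nonevent_mean_per_subject[sid]
            ne_vec = matrix_to_vector(ne) if ne.ndim == 2 else np.asarray(ne)
            records.append(
                {
                    "subject": sid,
                    "class": "nonevent",
                    "similarity_to_fc": float(np.corrcoef(ne_vec, fc_vec)[0, 1]),
                    "within_similarity": np.nan,
                }
            )
    return pd.DataFrame(records)


def paired_class_comparison(desc: pd.DataFrame, class_a: str, class_b: str):
    """Paired t-test of similarity-to-FC between two classes across subjects."""
    wide = desc.pivot_table(index="subject", columns="class", values="similarity_to_fc")
    both = wide.dropna(subset=[class_a, class_b])
    return ttest_rel(both[class_a], both[class_b])


def relative_frequency(
    labels_per_subject: dict[str, np.ndarray],
    total_valid_frames: dict[str, int],
    K: int,
) -> pd.DataFrame:
    """Per-subject event-pattern rate: count(label = k) / valid frames."""
    records = []
    for sid, labels in labels_per_subject.items():
        T = total_valid_frames[sid]
        if T <= 0:
            raise ValueError(f"subject {sid} has no valid frames")
        labels = np.asarray(labels)
        row = {"subject": sid}
        for k in range(1, K + 1):
            row[f"rate_{k}"] = float(np.sum(labels == k)) / T
        records.append(row)
    return pd.DataFrame(records)
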