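"""Frame identifiability and connectome-based predictive modeling (CPM).

Differential identifiability asks whether a subject's event frames look more
like each other than like other subjects' frames: from the frame-to-frame
Pearson similarity matrix, I_diff = (I_self - I_others) * 100, where I_self
averages within-subject (non-self) pairs and I_others between-subject pairs.

CPM predicts a phenotype from connectivity matrices with strict
cross-validation: within each training fold, edges whose correlation with
the phenotype passes p < p_thresh are split into positive and negative sets;
each subject is summarized by the two set sums; an ordinary least squares
model on the training sums is applied to the held-out subjects, and
performance is the correlation of held-out predictions with observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import FrameBank

__all__ = ["IdentifiabilityResult", "differential_identifiability", "cpm_fit_predict"]

logger = logging.getLogger(__name__)


@dataclass
class IdentifiabilityResult:
    i_self: float
    i_others: float

    @property
    def i_diff(self) -> float:
        return (self.i_self - self.i_others) * 100.0


def differential_identifiability(
    frames: np.ndarray | FrameBank, subject_ids: np.ndarray | None = None
) -> IdentifiabilityResult:
    """I_diff from a bank of frame edge-vectors and their subject labels.

    Subjects contributing a single frame enter only the between-subject term;
    if every subject is a singleton the within-subject mean is undefined and
    an error is raised.
    """
    if isinstance(frames, FrameBank):
        subject_ids = frames.subject_ids
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if len(np.unique(subject_ids)) < 2:
        raise ValueError("need at least 2 subjects")
    sim = np.corrcoef(frames)
    same = subject_ids[:, None] == subject_ids[None, :]
    np.fill_diagonal(same, False)
    iu = np.triu_indices(len(frames), k=1)
    within = sim[iu][same[iu]]
    between = sim[iu][~same[iu]]
    if within.size == 0:
        raise ValueError("every subject has a single frame; I_self undefined")
    return IdentifiabilityResult(i_self=float(within.mean()), i_others=float(between.mean()))


@dataclass
class CPMResult:
    predictions: np.ndarray
    observed: np.ndarray
    r: float
    pos_mask: np.ndarray  # edges ever selected positively (any fold)
    neg_mask: np.ndarray


def _edge_corr_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edgewise Pearson r and two-sided p of columns of X against y."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    sy = np.sqrt(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ Xc) / (sx * sy)
    r = np.nan_to_num(np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return r, p


def cpm_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    p_thresh: float = 0.01,
    cv: str = "loo",
    n_folds: int = 10,
    seed: int | np.random.Generator = 0,
) -> CPMResult:
    """Cross-validated CPM. ``X`` is n_subjects x n_edges (upper-triangle
    vectors of each subject's connectivity matrix), ``y`` the phenotype.

    ``cv``: "loo" (leave-one-out, deterministic fold order) or "kfold"
    (seeded shuffle into ``n_folds``). A fold selecting no edges predicts the
    training mean (logged). Feature selection and regression use training
    rows only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 subjects")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    if cv == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif cv == "kfold":
        rng = np.random.default_rng(seed)
        folds = np.array_split(rng.permutation(n), n_folds)
    else:
        raise ValueError(f"unknown cv scheme {cv!r}")

    preds = np.empty(n)
    pos_any = np.zeros(X.shape[1], dtype=bool)
    neg_any = np.zeros(X.shape[1], dtype=bool)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(n), test_idx)
        r, p = _edge_corr_p(X[train], y[train])
        pos = (p < p_thresh) & (r > 0)
        neg = (p < p_thresh) & (r < 0)
        pos_any |= pos
        neg_any |= neg
        if not pos.any() and not neg.any():
            logger.warning("fold selected no edges; predicting training mean")
            preds[test_idx] = y[train].mean()
            continue
        feats_train = np.column_stack(
            [X[train][:, pos].sum(axis=1), X[train][:, neg].sum(axis=1), np.ones(len(train))]
        )
        coef, *_ = np.linalg.lstsq(feats_train, y[train], rcond=None)
        feats_test = np.column_stack(
            [X[test_idx][:, pos].sum(axis=1), X[test_idx][:, neg].sum(axis=1), np.ones(len(test_idx))]
        )
        preds[test_idx] = feats_test @ coef
    if np.std(preds) == 0:
        r_obs = 0.0
    else:
        r_obs = float(np.corrcoef(preds, y)[0, 1])
    return CPMResult(predictions=preds, observed=y, r=r_obs, pos_mask=pos_any, neg_mask=neg_any)
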