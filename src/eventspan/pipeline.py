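"""End-to-end orchestration: simulate -> detect -> cluster -> downstream analyses.

The stage functions here are the library surface used by the command-line
interface, the test suite, and the acceptance script. ``run_pipeline`` runs
every stage from a config mapping, writes TSV outputs, and records a manifest
(config snapshot, per-stage seeds, output digests).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import (
    ClusterModel,
    FrameBank,
    _similarity_to_centroids,
    align_models,
    kmeans_fit,
    relative_frequency,
    sample_subjects,
    similarity_curve,
    subsample_frames,
)
from .communication import StructuralConnectome, coupling_matrix, extended_measures
from .edge_dynamics import (
    EventSet,
    amplitude_from_z,
    circular_shift_null,
    detect_events,
    AmplitudeSeries,
    matrix_to_vector,
    zscore_rows,
)
from .modularity import consensus_partition, frequency_weighted_Q, modularity_uniform
from .prediction import cpm_fit_predict, differential_identifiability
from .synthetic import CohortBundle, SyntheticCohortSpec, generate_cohort
from .edge_dynamics import vector_to_matrix

logger = logging.getLogger(__name__)


@dataclass
class SubjectEvents:
    """Cached per-subject detection results (edge vectors at event frames)."""

    subject_id: str
    event_vectors: np.ndarray  # n_events x n_pairs
    frame_indices: np.ndarray
    amplitudes: np.ndarray
    threshold: float
    fc_vec: np.ndarray
    nonevent_vec: np.ndarray
    n_frames: int
    true_labels: np.ndarray | None = None  # aligned to frame_indices; 0 = not planted


def detect_subject_events(
    ts, alpha: float = 0.05, n_null: int = 50, seed: int | np.random.Generator = 0,
    mode: str = "max",
) -> tuple[EventSet, np.ndarray, np.ndarray, np.ndarray]:
    """Detect one subject's events; returns (EventSet, event edge-vectors,
    static-FC vector, nonevent-mean vector).

    The default ``max`` mode thresholds at the null distribution of the
    per-realization maximum amplitude, so the flagged set stays in the
    sub-1%-of-frames selectivity regime characteristic of empirical event
    analyses; ``frame`` mode gives the per-frame alpha rule instead.
    """
    z = zscore_rows(ts)
    amp = AmplitudeSeries(values=amplitude_from_z(z.values))
    nulls = circular_shift_null(z, n_null=n_null, seed=seed)
    ev = detect_events(amp, nulls, alpha=alpha, mode=mode)
    T = z.n_frames
    vecs = np.stack(
        [matrix_to_vector(np.outer(z.values[:, f], z.values[:, f])) for f in ev.frame_indices]
    ) if ev.n_events else np.empty((0, z.n_nodes * (z.n_nodes - 1) // 2))
    fc_vec = matrix_to_vector((z.values @ z.values.T) / (T - 1))
    nonev = np.setdiff1d(np.arange(T), ev.frame_indices)
    zn = z.values[:, nonev]
    nonevent_vec = matrix_to_vector((zn @ zn.T) / max(len(nonev) - 1, 1))
    return ev, vecs, fc_vec, nonevent_vec


def detect_cohort_events(
    bundle: CohortBundle,
    alpha: float = 0.05,
    n_null: int = 50,
    seed: int = 0,
    mode: str = "max",
) -> dict[str, SubjectEvents]:
    """Run event detection for every subject in a synthetic cohort, aligning
    detected frames with the planted ground truth (label 0 = unplanted)."""
    root = np.random.SeedSequence(seed)
    streams = root.spawn(len(bundle.subjects))
    out: dict[str, SubjectEvents] = {}
    for s, ss in zip(bundle.subjects, streams):
        ev, vecs, fc_vec, nonevent_vec = detect_subject_events(
            s.ts, alpha=alpha, n_null=n_null, seed=np.random.default_rng(ss), mode=mode
        )
        truth = dict(zip(s.true_event_frames.tolist(), s.true_event_labels.tolist()))
        true_labels = np.array([truth.get(int(f), 0) for f in ev.frame_indices], dtype=int)
        out[s.subject_id] = SubjectEvents(
            subject_id=s.subject_id,
            event_vectors=vecs,
            frame_indices=ev.frame_indices,
            amplitudes=ev.amplitudes,
            threshold=ev.threshold,
            fc_vec=fc_vec,
            nonevent_vec=nonevent_vec,
            n_frames=s.ts.n_frames,
            true_labels=true_labels,
        )
    return out


def build_frame_bank(
    events: dict[str, SubjectEvents],
    cohort_table: pd.DataFrame,
    subjects: list[str],
    frames_per_subject: int,
    seed: int | np.random.Generator,
) -> FrameBank:
    """Pool up to ``frames_per_subject`` event frames from the given subject
    sample (duplicates allowed) into one bank."""
    rng = np.random.default_rng(seed)
    bins = dict(zip(cohort_table["subject"], cohort_table["age_bin"]))
    rows, sids, bin_ids, fidx = [], [], [], []
    for sid in subjects:
        se = events[sid]
        n = se.event_vectors.shape[0]
        if n == 0:
            logger.warning("subject %s has no detected events; skipped", sid)
            continue
        take = np.sort(rng.choice(n, size=min(frames_per_subject, n), replace=False))
        rows.append(se.event_vectors[take])
        sids.extend([sid] * len(take))
        bin_ids.extend([bins.get(sid, -1)] * len(take))
        fidx.extend(se.frame_indices[take].tolist())
    return FrameBank(
        frames=np.vstack(rows),
        subject_ids=np.asarray(sids),
        age_bin_ids=np.asarray(bin_ids),
        frame_indices=np.asarray(fidx),
    )


def cluster_repetitions(
    events: dict[str, SubjectEvents],
    cohort_table: pd.DataFrame,
    K_range=range(2, 11),
    metric: str = "pearson",
    repetitions: int = 10,
    frames_per_subject: int = 10,
    subjects_per_bin: int = 20,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[dict[int, list[ClusterModel]], pd.DataFrame, list[FrameBank]]:
    """The repeated sample->pool->cluster loop over a K range.

    Each repetition draws a fresh age-balanced subject sample (with
    replacement), pools up to ``frames_per_subject`` cached event frames per
    subject, and fits k-means at every K. Detections are cached; only the
    subject sampling and frame subsampling are redrawn.
    """
    root = np.random.SeedSequence(seed)
    models_per_K: dict[int, list[ClusterModel]] = {k: [] for k in K_range}
    banks: list[FrameBank] = []
    for rep_ss in root.spawn(repetitions):
        rng = np.random.default_rng(rep_ss)
        subjects = sample_subjects(cohort_table, subjects_per_bin, rng)
        bank = build_frame_bank(events, cohort_table, subjects, frames_per_subject, rng)
        banks.append(bank)
        for K in K_range:
            models_per_K[K].append(
                kmeans_fit(bank, K, metric=metric, n_restarts=n_restarts, seed=rng)
            )
    curve = similarity_curve(models_per_K)
    return models_per_K, curve, banks


def label_all_events(
    events: dict[str, SubjectEvents], centroids: np.ndarray, metric: str = "pearson"
) -> dict[str, np.ndarray]:
    """Assign every subject's detected event frames to the nearest centroid."""
    out = {}
    for sid, se in events.items():
        if se.event_vectors.shape[0] == 0:
            out[sid] = np.empty(0, dtype=int)
            continue
        sim = _similarity_to_centroids(se.event_vectors, centroids, metric)
        out[sid] = np.argmax(sim, axis=1) + 1
    return out


def match_clusters_to_templates(centroids: np.ndarray, templates) -> np.ndarray:
    """Permute centroid rows so cluster k corresponds to planted template k.

    Matches by linear assignment on 1 - corr(centroid, template mean edge
    pattern); returns the reordered centroids.
    """
    from scipy.optimize import linear_sum_assignment

    ref = np.stack([matrix_to_vector(t.mean_edge_pattern()) for t in templates])
    cost = 1.0 - _similarity_to_centroids(centroids, ref, "pearson")
    rows, cols = linear_sum_assignment(cost[:, : centroids.shape[0]])
    order = np.argsort(cols)
    return centroids[rows[order]]


def pattern_frequency_age(
    events: dict[str, SubjectEvents],
    labels_per_subject: dict[str, np.ndarray],
    cohort_table: pd.DataFrame,
    K: int = 2,
) -> pd.DataFrame:
    """Per-subject pattern rates merged with ages (one row per subject)."""
    totals = {sid: se.n_frames for sid, se in events.items()}
    rates = relative_frequency(labels_per_subject, totals, K)
    return rates.merge(cohort_table[["subject", "age", "age_bin", "phenotype"]], on="subject")


# ---------------------------------------------------------------------------
# config-driven runner


REQUIRED_STAGES = ("simulate", "detect", "cluster", "age_trends", "coupling", "modularity", "predict")


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timings: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "seeds": self.seeds,
                    "outputs": self.outputs,
                    "timings": self.timings,
                },
                fh,
                indent=2,
            )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_config(config: dict) -> dict:
    """Schema-check a pipeline config before any compute. Seeds are explicit:
    a missing seed is an error, never an implicit default."""
    if "seed" not in config:
        raise ValueError("config must set an explicit 'seed'")
    defaults = {
        "outdir": "eventspan_run",
        "n_nodes": 100,
        "n_frames": 900,
        "subjects_per_bin": 20,
        "alpha": 0.05,
        "n_null": 50,
        "k_min": 2,
        "k_max": 6,
        "metric": "pearson",
        "repetitions": 5,
        "frames_per_subject": 10,
        "n_perm": 1000,
        "q": 0.01,
        "n_spin": 500,
        "modularity_runs": 100,
        "gamma": 1.0,
        "p_thresh": 0.01,
        "cv": "loo",
    }
    out = {**defaults, **config}
    if not 0 < out["alpha"] < 1:
        raise ValueError("alpha must be in (0, 1)")
    if out["k_min"] < 1 or out["k_max"] < out["k_min"]:
        raise ValueError("invalid K range")
    if out["metric"] not in ("pearson", "lins_ccc"):
        raise ValueError(f"unknown metric {out['metric']!r}")
    return out


def run_pipeline(config: dict) -> RunManifest:
    """Execute the full synthetic-cohort analysis from a config mapping.

    Stages: simulate -> detect -> cluster -> age-trends -> coupling ->
    modularity -> predict. Writes TSV outputs and a JSON manifest under
    ``config['outdir']``.
    """
    from .age_effects import age_trend_with_null, system_block_average
    from .nulls import spin_permutations

    cfg = validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, version=__version__)
    root = np.random.SeedSequence(cfg["seed"])
    stage_seeds = {name: s.generate_state(1)[0] % (2**31) for name, s in
                   zip(REQUIRED_STAGES, root.spawn(len(REQUIRED_STAGES)))}
    manifest.seeds = {k: int(v) for k, v in stage_seeds.items()}

    def _stage(name):
        t0 = time.time()

        def done():
            manifest.timings[name] = round(time.time() - t0, 2)
            logger.info("stage %s done in %.1fs", name, manifest.timings[name])

        return done

    # simulate
    done = _stage("simulate")
    spec = SyntheticCohortSpec(
        n_nodes=cfg["n_nodes"],
        n_frames=cfg["n_frames"],
        subjects_per_bin=cfg["subjects_per_bin"],
        seed=int(stage_seeds["simulate"]),
    )
    bundle = generate_cohort(spec)
    bundle.table.to_csv(outdir / "cohort.tsv", sep="\t", index=False)
    done()

    # detect
    done = _stage("detect")
    events = detect_cohort_events(
        bundle, alpha=cfg["alpha"], n_null=cfg["n_null"], seed=int(stage_seeds["detect"])
    )
    ev_rows = [
        {"subject": sid, "frame": int(f), "amplitude": float(a)}
        for sid, se in events.items()
        for f, a in zip(se.frame_indices, se.amplitudes)
    ]
    pd.DataFrame(ev_rows).to_csv(outdir / "events.tsv", sep="\t", index=False)
    done()

    # cluster
    done = _stage("cluster")
    models_per_K, curve, _ = cluster_repetitions(
        events,
        bundle.table,
        K_range=range(cfg["k_min"], cfg["k_max"] + 1),
        metric=cfg["metric"],
        repetitions=cfg["repetitions"],
        frames_per_subject=cfg["frames_per_subject"],
        subjects_per_bin=cfg["subjects_per_bin"],
        seed=int(stage_seeds["cluster"]),
    )
    curve.to_csv(outdir / "similarity_curve.tsv", sep="\t", index=False)
    best_K = int(curve.loc[curve["mean_similarity"].idxmax(), "K"])
    aligned, ref_centroids = align_models(models_per_K[min(2, best_K) if 2 in models_per_K else best_K])
    K_used = aligned[0].K
    pd.DataFrame(ref_centroids).to_csv(
        outdir / f"centroids_K{K_used}.tsv", sep="\t", index=False, header=False
    )
    labels = label_all_events(events, ref_centroids, metric=cfg["metric"])
    done()

    # age trends
    done = _stage("age_trends")
    freq = pattern_frequency_age(events, labels, bundle.table, K=K_used)
    freq.to_csv(outdir / "pattern_frequency.tsv", sep="\t", index=False)
    trend = age_trend_with_null(
        freq[[f"rate_{k}" for k in range(1, K_used + 1)]].to_numpy(),
        freq["age"].to_numpy(),
        n_perm=cfg["n_perm"],
        q=cfg["q"],
        seed=int(stage_seeds["age_trends"]),
    )
    trend.to_csv(outdir / "frequency_age_trend.tsv", sep="\t", index=False)
    done()

    # coupling
    done = _stage("coupling")
    n = spec.n_nodes
    mean_sc = np.mean([s.sc for s in bundle.subjects], axis=0)
    sc = StructuralConnectome(weights=mean_sc, coords=bundle.coords, volumes=bundle.volumes)
    ensemble = extended_measures(sc)
    mean_event = {
        k: vector_to_matrix(
            np.vstack([events[sid].event_vectors[lab == k]
                       for sid, lab in labels.items() if np.any(lab == k)]).mean(axis=0), n)
        for k in range(1, K_used + 1)
    }
    coupling_rows = []
    for k, pat in mean_event.items():
        res = coupling_matrix(pat, ensemble)
        for i in range(n):
            row = {"cluster": k, "node": i}
            row.update(dict(zip(res.measure_names, res.r2[i])))
            coupling_rows.append(row)
    pd.DataFrame(coupling_rows).to_csv(outdir / "coupling_r2.tsv", sep="\t", index=False)
    done()

    # modularity
    done = _stage("modularity")
    q_rows = []
    partitions = {}
    for k, pat in mean_event.items():
        part, _ = consensus_partition(
            pat, gamma=cfg["gamma"], n_runs=cfg["modularity_runs"],
            seed=int(stage_seeds["modularity"]) + k, batch=20,
        )
        partitions[k] = part
        q_rows.append({"target": f"C{k}", "Q": part.Q, "n_modules": part.n_modules})
        pd.DataFrame({"node": np.arange(n), "module": part.labels}).to_csv(
            outdir / f"partition_C{k}.tsv", sep="\t", index=False
        )
    fc_mean = vector_to_matrix(
        np.mean([se.fc_vec for se in events.values()], axis=0), n)
    ne_mean = vector_to_matrix(
        np.mean([se.nonevent_vec for se in events.values()], axis=0), n)
    for name, mat in (("static_fc", fc_mean), ("nonevent", ne_mean)):
        part, _ = consensus_partition(
            mat, gamma=cfg["gamma"], n_runs=cfg["modularity_runs"],
            seed=int(stage_seeds["modularity"]), batch=20,
        )
        q_rows.append({"target": name, "Q": part.Q, "n_modules": part.n_modules})
    pd.DataFrame(q_rows).to_csv(outdir / "q_summary.tsv", sep="\t", index=False)
    done()

    # predict
    done = _stage("predict")
    subj_order = [s.subject_id for s in bundle.subjects]
    y = bundle.table.set_index("subject").loc[subj_order, "phenotype"].to_numpy()
    cpm_rows = []
    for cls in ["events", "C1", "C2", "nonevent"]:
        X = []
        keep = []
        for i, sid in enumerate(subj_order):
            se = events[sid]
            if cls == "nonevent":
                X.append(se.nonevent_vec)
                keep.append(i)
            elif cls == "events":
                if se.event_vectors.shape[0]:
                    X.append(se.event_vectors.mean(axis=0))
                    keep.append(i)
            else:
                k = int(cls[1])
                sel = labels[sid] == k
                if np.any(sel):
                    X.append(se.event_vectors[sel].mean(axis=0))
                    keep.append(i)
        res = cpm_fit_predict(
            np.vstack(X), y[keep], p_thresh=cfg["p_thresh"], cv=cfg["cv"],
            seed=int(stage_seeds["predict"]),
        )
        cpm_rows.append({"class": cls, "r": res.r, "n": len(keep)})
    pd.DataFrame(cpm_rows).to_csv(outdir / "cpm_summary.tsv", sep="\t", index=False)
    done()

    for path in sorted(outdir.glob("*.tsv")):
        manifest.outputs[path.name] = _digest(path)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def validate_inputs(paths: dict) -> list[str]:
    """Pre-compute validation of on-disk inputs; returns a list of problems.

    Checks matrix shapes, SC symmetry, node-count consistency between the
    time series and ``nodes.tsv``, and NaNs anywhere.
    """
    report: list[str] = []
    nodes = None
    if "nodes" in paths:
        nodes = pd.read_csv(paths["nodes"], sep="\t")
        need = {"node", "system", "x", "y", "z", "volume"}
        missing = need - set(nodes.columns)
        if missing:
            report.append(f"nodes.tsv missing columns: {sorted(missing)}")
    for key, path in paths.items():
        if key in ("nodes", "cohort"):
            continue
        mat = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        if np.isnan(mat).any():
            report.append(f"{key}: contains NaN")
        if key.endswith("sc"):
            if mat.shape[0] != mat.shape[1]:
                report.append(f"{key}: SC not square {mat.shape}")
            elif not np.allclose(mat, mat.T, atol=1e-8):
                report.append(f"{key}: SC not symmetric")
            if nodes is not None and mat.shape[0] != len(nodes):
                report.append(f"{key}: {mat.shape[0]} nodes vs nodes.tsv {len(nodes)}")
        if key.endswith("ts") and nodes is not None and mat.shape[0] != len(nodes):
            report.append(f"{key}: {mat.shape[0]} rows vs nodes.tsv {len(nodes)}")
    return report
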