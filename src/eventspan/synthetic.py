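"""Synthetic lifespan cohort generator with planted co-fluctuation events.

Emulates the statistical structure of a cross-sectional resting-state cohort
(ages 6-75, seven 10-year bins): per-subject nodal time series consisting of
weakly correlated baseline noise plus sparse high-amplitude activation bursts
drawn from two event templates whose relative frequencies trend oppositely
with age; a distance-dependent weighted structural connectome on a spherical
node geometry; and a phenotype linearly related to each subject's true
pattern-2 event fraction.

An event frame is a rank-1 activation burst: x(t) = A * sqrt(N) * s * w with
w a unit-norm template component, s = +/-1, so the edge co-fluctuation
pattern of the frame is proportional to w w^T regardless of s. The amplitude
A is therefore expressed in units of per-node baseline SD (a node carrying a
typical template weight deflects by about A standard deviations), which is
what makes the bursts *high-amplitude* relative to baseline.

All randomness descends from a single seed through ``numpy`` SeedSequence
spawning: one child stream for geometry, one per subject (time series, SC,
age jitter), one for phenotype noise, in that fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .edge_dynamics import NodeTimeSeries

__all__ = [
    "SyntheticCohortSpec",
    "EventTemplate",
    "SubjectRecord",
    "CohortBundle",
    "CANONICAL_SYSTEMS",
    "make_templates",
    "generate_subject_run",
    "generate_geometry_and_sc",
    "generate_cohort",
    "write_cohort",
]

CANONICAL_SYSTEMS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "control",
    "default_mode",
    "temporoparietal",
)

DEFAULT_AGE_BINS = tuple((6 + 10 * k, 16 + 10 * k) for k in range(7))


@dataclass
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    ``event_rate_*`` are expected events per run at the age extremes (the
    default 6/900 frames = 0.67% of frames sits inside the 0.1-1% band
    typical of empirical event rates); ``pattern_mix_*`` give the probability
    that an event is pattern 1 at the youngest/oldest age, interpolated
    linearly in age in between.
    """

    n_nodes: int = 100
    n_frames: int = 900
    tr_seconds: float = 0.645
    age_bins: tuple = DEFAULT_AGE_BINS
    subjects_per_bin: int = 20
    n_systems: int = 8
    event_rate_young: float = 6.0
    event_rate_old: float = 6.0
    pattern_mix_young: float = 0.7
    pattern_mix_old: float = 0.2
    event_amplitude: float = 3.0
    noise_sd: float = 1.0
    modular_cov: float = 0.02  # weak within-system baseline covariance
    sc_decay_lambda: float = 30.0  # mm
    sc_density: float = 0.3
    sc_gamma_shape: float = 4.0
    phenotype_beta: float = 20.0
    phenotype_age_gamma: float = 0.1
    phenotype_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pattern_mix_young", "pattern_mix_old", "sc_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        bins = [tuple(b) for b in self.age_bins]
        for (lo, hi) in bins:
            if hi <= lo:
                raise ValueError(f"degenerate age bin [{lo}, {hi})")
        for (_, hi), (lo2, _) in zip(bins, bins[1:]):
            if lo2 < hi:
                raise ValueError("age bins must be ordered and non-overlapping")
        self.age_bins = tuple(bins)
        max_rate = max(self.event_rate_young, self.event_rate_old)
        if self.n_frames <= 10 * max_rate:
            raise ValueError("n_frames must exceed 10x the expected event count")

    @property
    def age_range(self) -> tuple[float, float]:
        return self.age_bins[0][0], self.age_bins[-1][1]


@dataclass
class EventTemplate:
    """A planted event pattern: a mixture of unit-norm activation vectors."""

    id: int
    components: list[np.ndarray]
    component_probs: np.ndarray

    def __post_init__(self) -> None:
        self.components = [np.asarray(c, dtype=float) for c in self.components]
        self.component_probs = np.asarray(self.component_probs, dtype=float)
        if not np.isclose(self.component_probs.sum(), 1.0):
            raise ValueError("component_probs must sum to 1")
        for c in self.components:
            if not np.isclose(np.linalg.norm(c), 1.0):
                raise ValueError("each component must have unit Euclidean norm")

    def mean_edge_pattern(self) -> np.ndarray:
        """Probability-weighted mean of the components' outer products."""
        n = len(self.components[0])
        out = np.zeros((n, n))
        for p, c in zip(self.component_probs, self.components):
            out += p * np.outer(c, c)
        np.fill_diagonal(out, 0.0)
        return out


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    age_bin: int
    ts: NodeTimeSeries
    sc: np.ndarray
    true_event_frames: np.ndarray
    true_event_labels: np.ndarray
    phenotype: float = np.nan

    @property
    def f2(self) -> float:
        """True fraction of this subject's events that are pattern 2."""
        if len(self.true_event_labels) == 0:
            return 0.0
        return float(np.mean(self.true_event_labels == 2))


@dataclass
class CohortBundle:
    spec: SyntheticCohortSpec
    subjects: list[SubjectRecord]
    coords: np.ndarray
    volumes: np.ndarray
    system_labels: np.ndarray  # per-node system name
    templates: tuple[EventTemplate, EventTemplate]
    table: pd.DataFrame = field(default=None)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def make_templates(
    system_labels: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[EventTemplate, EventTemplate]:
    """Build the two planted event templates from the system assignment.

    Template 2 is a single bipartite component: +1 on the higher-order
    (heteromodal) systems — the last 3/8 of the system order (control,
    default mode, temporoparietal under the canonical naming) — and -1 on
    the unimodal/attention systems, so its mean edge pattern is rank-1 and
    its leading principal component captures nearly all variance.

    Template 1 is a discrete cone of components u1 + delta (cos(phi) u2 +
    sin(phi) u3) sampled at 8 angles phi, where u1, u2, u3 are localized
    bipartite motifs with disjoint supports (each contrasts a small positive
    group against a large negative one inside one third of the node order).
    Every component shares the dominant motif u1, so the cluster is
    internally cohesive and recoverable as ONE pattern, while the circular
    spread over u2/u3 has no preferred split axis, so carving it into
    sub-clusters is unstable across runs. The mean edge pattern
    [u1 u1' + (delta^2/2)(u2 u2' + u3 u3')] / (1 + delta^2) is rank 3 with a
    Gram-eigenvalue share below 0.9 at delta = 0.75, and its three disjoint
    unbalanced bipartite blocks (zero weight between thirds, positive mass
    dominating within) make it more modular under a uniform null than the
    near-balanced bipartite template 2.
    """
    system_labels = np.asarray(system_labels)
    systems = list(dict.fromkeys(system_labels))
    if len(systems) < 4:
        raise ValueError(f"need at least 4 distinct systems, got {len(systems)}")
    n = len(system_labels)

    # template 2: heteromodal (last 3/8 of the system order) vs the rest
    n_higher = max(1, (len(systems) * 3) // 8)
    higher_order = set(systems[-n_higher:])
    w2 = np.where(np.isin(system_labels, list(higher_order)), 1.0, -1.0)
    w2 /= np.linalg.norm(w2)
    t2 = EventTemplate(id=2, components=[w2], component_probs=np.array([1.0]))

    # template 1: cone of mixtures of three disjoint localized bipartite
    # motifs; each motif contrasts a small (+) against a large (-) group so
    # that positive within-group pair mass dominates the negative cross mass
    motifs = []
    for third in np.array_split(np.arange(n), 3):
        u = np.zeros(n)
        k = len(third) // 5
        u[third[:k]], u[third[k:]] = +1.0, -1.0
        motifs.append(u / np.linalg.norm(u))
    u1, u2, u3 = motifs
    delta, n_cone = 0.75, 8
    phis = 2.0 * np.pi * (np.arange(n_cone) + 0.5) / n_cone
    comps = [u1 + delta * (np.cos(p) * u2 + np.sin(p) * u3) for p in phis]
    comps = [c / np.linalg.norm(c) for c in comps]
    t1 = EventTemplate(
        id=1, components=comps, component_probs=np.full(n_cone, 1.0 / n_cone)
    )
    return t1, t2


def _system_block_matrix(system_labels: np.ndarray) -> np.ndarray:
    lab = np.asarray(system_labels)
    return (lab[:, None] == lab[None, :]).astype(float)


def _default_system_labels(n_nodes: int, n_systems: int) -> np.ndarray:
    names = list(CANONICAL_SYSTEMS)
    while len(names) < n_systems:
        names.append(f"system{len(names) + 1}")
    blocks = np.array_split(np.arange(n_nodes), n_systems)
    labels = np.empty(n_nodes, dtype=object)
    for name, block in zip(names, blocks):
        labels[block] = name
    return labels.astype(str)


def _pattern1_prob(spec: SyntheticCohortSpec, age: float) -> float:
    lo, hi = spec.age_range
    frac = np.clip((age - lo) / (hi - lo), 0.0, 1.0)
    return spec.pattern_mix_young + frac * (spec.pattern_mix_old - spec.pattern_mix_young)


def _event_rate(spec: SyntheticCohortSpec, age: float) -> float:
    lo, hi = spec.age_range
    frac = np.clip((age - lo) / (hi - lo), 0.0, 1.0)
    return spec.event_rate_young + frac * (spec.event_rate_old - spec.event_rate_young)


def _sample_event_frames(
    rng: np.random.Generator, n_frames: int, n_events: int, min_sep: int = 5
) -> np.ndarray:
    if n_events * min_sep >= n_frames:
        raise ValueError(
            f"{n_events} events with min separation {min_sep} do not fit in {n_frames} frames"
        )
    chosen: list[int] = []
    order = rng.permutation(n_frames)
    for f in order:
        if all(abs(f - c) >= min_sep for c in chosen):
            chosen.append(int(f))
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events:
        raise ValueError("could not place events with the requested separation")
    return np.sort(np.asarray(chosen, dtype=int))


def generate_subject_run(
    spec: SyntheticCohortSpec,
    age: float,
    templates: tuple[EventTemplate, EventTemplate],
    seed: int | np.random.Generator,
    system_labels: np.ndarray | None = None,
) -> tuple[NodeTimeSeries, np.ndarray, np.ndarray]:
    """One subject's run: correlated baseline noise plus planted event bursts.

    Returns (raw time series, true event frame indices, true event labels).
    """
    lo, hi = spec.age_range
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside covered range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    if system_labels is None:
        system_labels = _default_system_labels(spec.n_nodes, spec.n_systems)

    n, T = spec.n_nodes, spec.n_frames
    c = spec.modular_cov
    cov = c * _system_block_matrix(system_labels)
    np.fill_diagonal(cov, spec.noise_sd**2 + c)
    L = np.linalg.cholesky(cov)
    x = L @ rng.standard_normal((n, T))

    n_events = int(rng.poisson(_event_rate(spec, age)))
    if n_events == 0:
        return NodeTimeSeries(values=x), np.empty(0, dtype=int), np.empty(0, dtype=int)
    frames = _sample_event_frames(rng, T, n_events)
    p1 = _pattern1_prob(spec, age)
    labels = np.where(rng.random(n_events) < p1, 1, 2)
    t1, t2 = templates
    for f, lab in zip(frames, labels):
        tpl = t1 if lab == 1 else t2
        k = rng.choice(len(tpl.components), p=tpl.component_probs)
        s = rng.choice([-1.0, 1.0])
        x[:, f] += spec.event_amplitude * np.sqrt(n) * s * tpl.components[k]
    return NodeTimeSeries(values=x), frames, labels


def _fibonacci_sphere(n: int, radius: float = 100.0) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    theta = phi * i
    return radius * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _sc_from_distance(
    spec: SyntheticCohortSpec, dist: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Distance-decaying gamma-noised weights, thresholded to density, connected."""
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    shape = spec.sc_gamma_shape
    gain = rng.gamma(shape, 1.0 / shape, size=len(iu[0]))  # mean 1
    w = np.exp(-dist[iu] / spec.sc_decay_lambda) * gain

    keep = np.zeros(len(w), dtype=bool)
    n_keep = max(int(round(spec.sc_density * len(w))), n - 1)
    keep[np.argsort(w)[::-1][:n_keep]] = True

    # repair connectivity by re-adding maximum-weight spanning edges
    full = np.zeros((n, n))
    full[iu] = w
    full += full.T
    sparse_w = np.where(keep, w, 0.0)
    sc = np.zeros((n, n))
    sc[iu] = sparse_w
    sc += sc.T
    n_comp, _ = connected_components(csr_matrix(sc), directed=False)
    if n_comp > 1:
        recip = np.zeros_like(full)
        nz = full > 0
        recip[nz] = 1.0 / full[nz]
        mst = minimum_spanning_tree(csr_matrix(recip))
        mi, mj = mst.nonzero()
        sc[mi, mj] = full[mi, mj]
        sc[mj, mi] = full[mj, mi]
        n_comp, _ = connected_components(csr_matrix(sc), directed=False)
        if n_comp > 1:
            raise ValueError("could not connect SC at the requested density")
    return sc


def generate_geometry_and_sc(
    spec: SyntheticCohortSpec, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Shared node geometry plus one SC draw.

    Returns (coords [n x 3, mm on a 100 mm sphere], volumes [mm^3],
    SC weights [symmetric, zero diagonal, connected], system labels).
    """
    if spec.n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    rng = np.random.default_rng(seed)
    coords = _fibonacci_sphere(spec.n_nodes)
    volumes = rng.lognormal(mean=np.log(1500.0), sigma=0.3, size=spec.n_nodes)
    dist = squareform(pdist(coords))
    sc = _sc_from_distance(spec, dist, rng)
    labels = _default_system_labels(spec.n_nodes, spec.n_systems)
    return coords, volumes, sc, labels


def generate_cohort(spec: SyntheticCohortSpec) -> CohortBundle:
    """Generate the full cohort: geometry, per-subject runs and SCs, phenotypes."""
    root = np.random.SeedSequence(spec.seed)
    n_subj = len(spec.age_bins) * spec.subjects_per_bin
    geom_ss, pheno_ss, *subj_ss = root.spawn(2 + n_subj)

    coords, volumes, _, system_labels = generate_geometry_and_sc(
        spec, np.random.default_rng(geom_ss)
    )
    dist = squareform(pdist(coords))
    templates = make_templates(system_labels, seed=np.random.default_rng(geom_ss.spawn(1)[0]))

    subjects: list[SubjectRecord] = []
    idx = 0
    for b, (lo, hi) in enumerate(spec.age_bins):
        for _ in range(spec.subjects_per_bin):
            rng = np.random.default_rng(subj_ss[idx])
            age = float(rng.uniform(lo, hi))
            ts, frames, labels = generate_subject_run(
                spec, age, templates, rng, system_labels=system_labels
            )
            sc = _sc_from_distance(spec, dist, rng)
            subjects.append(
                SubjectRecord(
                    subject_id=f"sub-{idx:04d}",
                    age=age,
                    age_bin=b,
                    ts=ts,
                    sc=sc,
                    true_event_frames=frames,
                    true_event_labels=labels,
                )
            )
            idx += 1

    pheno_rng = np.random.default_rng(pheno_ss)
    for s in subjects:
        s.phenotype = (
            spec.phenotype_beta * s.f2
            + spec.phenotype_age_gamma * s.age
            + pheno_rng.normal(0.0, spec.phenotype_noise_sd)
        )

    table = pd.DataFrame(
        {
            "subject": [s.subject_id for s in subjects],
            "age": [s.age for s in subjects],
            "age_bin": [s.age_bin for s in subjects],
            "phenotype": [s.phenotype for s in subjects],
            "n_events": [len(s.true_event_frames) for s in subjects],
            "f2": [s.f2 for s in subjects],
        }
    )
    return CohortBundle(
        spec=spec,
        subjects=subjects,
        coords=coords,
        volumes=volumes,
        system_labels=system_labels,
        templates=templates,
        table=table,
    )


def write_cohort(bundle: CohortBundle, outdir) -> dict:
    """Write the cohort to plain TSV/JSON files; returns the truth manifest."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        {
            "node": [f"node{i:03d}" for i in range(bundle.spec.n_nodes)],
            "system": bundle.system_labels,
            "x": bundle.coords[:, 0],
            "y": bundle.coords[:, 1],
            "z": bundle.coords[:, 2],
            "volume": bundle.volumes,
        }
    )
    nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
    bundle.table[["subject", "age", "phenotype"]].to_csv(
        outdir / "cohort.tsv", sep="\t", index=False
    )
    truth: dict = {"seed": bundle.spec.seed, "subjects": {}}
    for s in bundle.subjects:
        pd.DataFrame(s.ts.values).to_csv(
            outdir / f"{s.subject_id}_ts.tsv", sep="\t", index=False, header=False
        )
        pd.DataFrame(s.sc).to_csv(
            outdir / f"{s.subject_id}_sc.tsv", sep="\t", index=False, header=False
        )
        truth["subjects"][s.subject_id] = {
            "age": s.age,
            "event_frames": s.true_event_frames.tolist(),
            "event_labels": s.true_event_labels.tolist(),
        }
    truth["templates"] = {
        f"template{t.id}": [c.tolist() for c in t.components] for t in bundle.templates
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh)
    return truth
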