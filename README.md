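# eventspan

High-amplitude co-fluctuation **events** in functional brain time series, analyzed
across the lifespan: detection, clustering into recurring patterns, age trends,
coupling with structural-connectome communication measures, modularity, and
phenotype prediction — with a first-class synthetic lifespan cohort generator so
the whole pipeline is testable without access to restricted neuroimaging data.

## Who this is for

Network neuroscientists working with resting-state fMRI parcellated to node
time series, and methodologists who want a tested, seeded re-implementation of
the edge-time-series event pipeline to run on their own data (plain TSV in,
plain TSV out) or to benchmark against planted ground truth.

## The model

For z-scored nodal activity `z_i(t)` the **edge time series** (ETS) is the
framewise decomposition of the Pearson correlation:

```
e_ij(t) = z_i(t) · z_j(t),          FC_ij = 1/(T−1) · Σ_t e_ij(t)
```

so static functional connectivity is exactly the time average of the ETS. The
per-frame global co-fluctuation amplitude is the root-sum-square over node
pairs, `RSS(t) = sqrt(Σ_{i<j} e_ij(t)²)`. **Events** are frames whose
amplitude significantly exceeds a circular-shift surrogate null (each node's
series independently rotated in time — marginals preserved exactly,
inter-node alignment destroyed). Event frames are pooled over an age-balanced
subject sample and clustered with similarity k-means (Pearson or Lin's
concordance `ρ_c = 2·cov(x,y) / (var x + var y + (mean x − mean y)²)`), with
cluster labels aligned across repetitions by Hungarian assignment on centroid
dissimilarity. Downstream analyses: pattern frequencies vs. age against an
age-randomized permutation null with Benjamini–Hochberg FDR; per-node variance
of event patterns explained by SC-derived communication measures (Euclidean
distance, binary/weighted communicability `exp(D^{−1/2} A D^{−1/2})`,
shortest-path lengths, mean first passage time, search information) with
spherical spin-test nulls; uniform-null modularity
`Q = Σ_{i<j, same module}(W_ij − γ·W̄) / Σ_{i<j}|W_ij|` maximized by seeded
generalized Louvain with co-assignment consensus; differential identifiability
`I_diff = (I_self − I_others)·100`; and connectome-based predictive modeling
(CPM) of phenotypes from subject-mean event patterns.

The synthetic cohort plants all of this structure: two event templates whose
relative frequencies trend oppositely with age across seven 10-year bins
(ages 6–75), a distance-dependent weighted structural connectome on a
spherical geometry, and a phenotype linear in each subject's true pattern-2
event fraction. See `docs/methods.md` for the generator's assumptions and
limitations.

## Worked example

```python
import numpy as np
from eventspan.synthetic import SyntheticCohortSpec, generate_cohort
from eventspan.pipeline import detect_subject_events

spec = SyntheticCohortSpec(n_nodes=100, n_frames=900, subjects_per_bin=1, seed=7)
bundle = generate_cohort(spec)
subject = bundle.subjects[3]
events, vectors, fc_vec, _ = detect_subject_events(subject.ts, alpha=0.05,
                                                   n_null=50, seed=0)
print(f"subject age: {subject.age:.1f} y")
print(f"planted events: {list(subject.true_event_frames)}")
print(f"detected events: {list(events.frame_indices)}")
print(f"amplitude threshold: {events.threshold:.1f}")
print(f"event amplitudes: {np.round(events.amplitudes, 1)}")
sim = [float(np.corrcoef(v, fc_vec)[0, 1]) for v in vectors]
print(f"event-frame similarity to static FC: {np.round(sim, 2)}")
```

prints

```
subject age: 42.3 y
planted events: [386, 720, 771]
detected events: [386, 720, 771]
amplitude threshold: 119.1
event amplitudes: [633.  663.5 683.3]
event-frame similarity to static FC: [0.55 0.56 0.39]
```

The three planted high-amplitude frames are recovered exactly: their
co-fluctuation amplitudes (633–683) sit far above the familywise null
threshold (119), and each single frame already correlates 0.4–0.6 with the
subject's full static FC — the disproportionate contribution of events to
time-averaged connectivity that motivates the whole analysis.

There is also a CLI for file-based workflows:

```
eventspan simulate --n-nodes 100 --n-frames 900 --subjects-per-bin 20 --seed 1 --outdir cohort/
eventspan detect-events --ts cohort/sub-0000_ts.tsv --alpha 0.05 --n-null 100 --seed 2 --out events.tsv
eventspan run-all --config config.yaml
```

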