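"""Shared fixtures: synthetic cohorts at two scales and cached detections.

The small cohort keeps unit tests fast; the full-scale cohort (100 nodes,
900 frames, 7 x 20 subjects — the generator's default study conditions) is
session-scoped and shared by the end-to-end recovery tests.
"""

import numpy as np
import pytest

from eventspan.pipeline import cluster_repetitions, detect_cohort_events
from eventspan.synthetic import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    spec = SyntheticCohortSpec(n_nodes=60, n_frames=400, subjects_per_bin=6, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_events(small_cohort):
    return detect_cohort_events(small_cohort, alpha=0.05, n_null=20, seed=12)


@pytest.fixture(scope="session")
def full_cohort():
    return generate_cohort(SyntheticCohortSpec(seed=101))


@pytest.fixture(scope="session")
def full_events(full_cohort):
    return detect_cohort_events(full_cohort, alpha=0.05, n_null=20, seed=102)


@pytest.fixture(scope="session")
def full_cluster_runs(full_cohort, full_events):
    """The repeated sample->cluster loop at K = 2..10, R = 10 repetitions."""
    return cluster_repetitions(
        full_events,
        full_cohort.table,
        K_range=range(2, 11),
        repetitions=10,
        frames_per_subject=10,
        subjects_per_bin=20,
        seed=103,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
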