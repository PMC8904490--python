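"""Shared fixtures: small synthetic cohorts generated at test time."""

import dataclasses

import numpy as np
import pytest

from cnmir.io_formats import segments_by_sample
from cnmir.synthetic_data import SimConfig, generate_cohort


# A reduced cohort for unit tests: same structure as the default desk
# fixture but cheaper (fewer genes/null features), so stage-level tests run
# in seconds.
MINI_CONFIG = SimConfig(
    n_samples=100,
    n_genes=80,
    n_mirnas=12,
    n_regions=2,
    n_true_edges=2,
    cis_genes_per_region=3,
    cis_mirnas_per_region=2,
    decoys_per_region=2,
    n_tfs=3,
    tf_targets_per_tf=4,
    seed=11,
)


@pytest.fixture(scope="session")
def mini_cohort():
    return generate_cohort(MINI_CONFIG)


@pytest.fixture(scope="session")
def desk_cohort():
    """The full default study-condition cohort (150 samples, 300 genes)."""
    return generate_cohort(dataclasses.replace(SimConfig(), seed=5))


@pytest.fixture(scope="session")
def mini_segs(mini_cohort):
    return segments_by_sample(mini_cohort.segments)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
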