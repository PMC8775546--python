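import numpy as np
import pytest

from kinentropy import CohortSpec, make_fixture, simulate_cohort


@pytest.fixture(scope="session")
def minimal_symmetric_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_minimal")
    return make_fixture("minimal_symmetric", out)


@pytest.fixture(scope="session")
def small_cohort_manifest(tmp_path_factory):
    """5 participants x 2 dances x both sides, knee + hip flexion, 30 s."""
    out = tmp_path_factory.mktemp("small_cohort")
    spec = CohortSpec(
        n_pd=5, n_oa=0, dances=("tango", "waltz"), recordings_per_dance=1,
        duration_min_range=(0.5, 0.5),
        channels=(("knee", "flexion"), ("hip", "flexion")),
        seed=7,
    )
    return simulate_cohort(spec, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220101)
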