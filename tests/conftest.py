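import numpy as np
import pytest
from hypothesis import settings

import avalanchebci as ab

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def epochs(signals, conditions, outcomes=None, fs=250.0, subject_id="test"):
    return ab.EpochedSourceData(
        subject_id=subject_id,
        signals=np.asarray(signals),
        sampling_rate_hz=fs,
        condition_labels=np.asarray(conditions),
        outcome_labels=None if outcomes is None else np.asarray(outcomes),
    )


@pytest.fixture(scope="session")
def small_gt():
    return ab.make_ground_truth(n_regions=19, n_planted=8, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_gt):
    spec = ab.CohortSpec(n_subjects=3, n_trials_per_condition=12, seed=5).small()
    return ab.make_cohort(spec, small_gt)


@pytest.fixture(scope="session")
def small_atm_sets(small_cohort):
    return [ab.extract_trial_atms(rec.data) for rec in small_cohort.subjects]
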