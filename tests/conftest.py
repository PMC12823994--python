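import numpy as np
import pytest

from tcrdiv import CloneTable, SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """A 5,000-subject synthetic cohort (metrics only) under default settings."""
    return simulate_cohort(SimulationParams(n_subjects=5000, seed=11), materialize=False).metrics


@pytest.fixture
def toy_table():
    return CloneTable(
        subject_id="toy", clone_ids=("c1", "c2", "c3"), templates=np.array([5, 3, 2])
    )


def make_table(counts, subject_id="t"):
    counts = np.asarray(counts, np.int64)
    ids = tuple(f"c{i}" for i in range(len(counts)))
    return CloneTable(subject_id=subject_id, clone_ids=ids, templates=counts)
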