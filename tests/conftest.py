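import numpy as np
import pandas as pd
import pytest

from eegate import chain_montage, default_montage, synth_cohort, toy_grid_montage


@pytest.fixture(scope="session")
def montage61():
    return default_montage()


@pytest.fixture(scope="session")
def chain8():
    return chain_montage(8)


@pytest.fixture(scope="session")
def grid22():
    return toy_grid_montage(2, 2)


@pytest.fixture(scope="session")
def cohort40():
    cohort, panels = synth_cohort(40, seed=11)
    return cohort, panels


def make_accuracy_table(rng, n_subjects=40, mean=0.9, sd=0.05,
                        conditions=("ignore", "update", "control_short", "control_long")):
    """Null accuracy table: independent Gaussian accuracies per cell."""
    rows = [dict(subject=f"s{i:03d}", condition=c,
                 accuracy=float(np.clip(rng.normal(mean, sd), 0, 1)), n_trials=32)
            for i in range(n_subjects) for c in conditions]
    return pd.DataFrame(rows)


@pytest.fixture
def null_accuracy():
    return make_accuracy_table(np.random.default_rng(7))
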