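import logging

import numpy as np
import pytest

from dyadphys.behavior import assemble_dataset
from dyadphys.pipeline import FEATURE_COLUMNS, build_trial_table
from dyadphys.synthetic import CohortConfig, generate_cohort

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_cohort():
    """2 dyads x 1 day x 2 trials/condition: 16 trial records."""
    cfg = CohortConfig(n_dyads=2, days=1, trials_per_condition_per_day=2,
                       trial_duration=90.0, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    _, records = small_cohort
    return build_trial_table(records)


@pytest.fixture(scope="session")
def medium_table():
    """7 dyads x 1 day x 7 trials/condition with autonomic coupling."""
    cfg = CohortConfig(n_dyads=7, days=1, trials_per_condition_per_day=7,
                       coupling_autonomic=0.9, coupling_error=0.1,
                       trial_duration=90.0, seed=11)
    return build_trial_table(generate_cohort(cfg))


def make_gaussian_dataset(rng, n_per_class=40, n_classes=3, n_informative=2,
                          n_noise=0, separation=3.0):
    """Well-separated Gaussian blobs plus optional pure-noise columns."""
    X, y = [], []
    d = n_informative + n_noise
    for c in range(n_classes):
        mu = np.zeros(d)
        mu[:n_informative] = separation * c
        X.append(mu + rng.standard_normal((n_per_class, d)))
        y.extend([c] * n_per_class)
    return np.vstack(X), np.asarray(y)


@pytest.fixture
def gaussian_dataset():
    return make_gaussian_dataset(np.random.default_rng(3))


def cell_dataset(table, kind="R1", condition="collaborative",
                 predictor="autonomic", **kw):
    return assemble_dataset(table, kind, condition, predictor,
                            feature_columns=list(FEATURE_COLUMNS), **kw)
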