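"""Shared fixtures. The expensive simulation products (shuffled-pair null,
classification cohorts) are session-scoped so the classification and
calibration checks reuse one set of study-condition simulations."""

import numpy as np
import pytest

from optocorr import pipelines as pl
from optocorr import rampcorr as rc


@pytest.fixture(scope="session")
def null_sessions():
    """Twenty independent simulated recordings (two unshared cells each),
    preprocessed once for shuffled-pair assembly."""
    return pl.independent_sessions(20, seed=11)


@pytest.fixture(scope="session")
def null_thresholds(null_sessions):
    """Coordination thresholds from 1000 shuffled cross-recording pairs."""
    return rc.shuffle_null(null_sessions, n_pairs=1000, seed=12,
                           stim_duration_ms=8000.0)


@pytest.fixture(scope="session")
def labelled_cohort():
    """50 fully shared and 50 independent simulated pairs (10 seeds)."""
    return pl.classification_cohort(n_seeds=10, shared_per_seed=5,
                                    independent_per_seed=5, seed=13)


@pytest.fixture(scope="session")
def fresh_independent_pairs():
    """100 independent pairs not used to build the null."""
    return pl.classification_cohort(n_seeds=10, shared_per_seed=0,
                                    independent_per_seed=10, seed=14)
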