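"""Shared fixtures: one trained model set and one analyzed default cohort.

Training the clocks and subset estimators is the expensive step, so it is
done once per session; tests that need different generative settings
simulate their own small cohorts.
"""

from dataclasses import replace

import numpy as np
import pytest

from epiaccel import SimConfig, simulate_cohort
from epiaccel.experiments import analyze_cohort, child_seeds, train_models

MASTER_SEED = 1


@pytest.fixture(scope="session")
def models():
    return train_models(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def default_cohort(models):
    """Default single-group cohort sharing the trained models' probe universe."""
    cfg = replace(SimConfig(), probe_seed=models.probe_seed, seed=child_seeds(MASTER_SEED, 4)[3])
    beta, annotation, truth = simulate_cohort(cfg)
    return beta, annotation, truth


@pytest.fixture(scope="session")
def analyzed(models, default_cohort):
    beta, annotation, truth = default_cohort
    accel, counts, dnam_age, blood_age = analyze_cohort(
        models, beta, annotation, reference_group="A"
    )
    return {
        "accel": accel,
        "counts": counts,
        "dnam_age": dnam_age,
        "blood_age": blood_age,
        "annotation": annotation,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
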