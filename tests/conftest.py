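import numpy as np
import pytest

import cortvowel as cv
from cortvowel import inverse, simulate


@pytest.fixture(scope="session")
def source20():
    """Small source space with lead field (20 vertices, 10 ROIs)."""
    src = cv.build_source_space(20, 10, seed=3)
    cv.compute_lead_field(src)
    return src


@pytest.fixture(scope="session")
def source60():
    src = cv.build_source_space(60, 30, seed=1)
    cv.compute_lead_field(src)
    return src


@pytest.fixture(scope="session")
def focal_experiment(source20):
    """Strong focal experiment: low background, one active vertex per vowel."""
    truth = simulate.default_ground_truth(source20, n_active=1, snr=20, seed=4)
    design = simulate.ExperimentDesign(n_trials_per_task=10, background_std=0.1)
    epochs, currents = cv.simulate_experiment(source20, truth, design, seed=5)
    return truth, epochs, currents


@pytest.fixture(scope="session")
def default_windows():
    return inverse.WindowSpec((0.5, 2.5))


@pytest.fixture(scope="session")
def study_dataset():
    """One study-conditions dataset (default noise levels, 20 trials/task)."""
    cfg = cv.RunConfig(seed=11, n_trials_per_task=20)
    ds = cv.pipeline.make_dataset(cfg)
    prior = cv.pipeline.priors_from_dataset(ds, cfg)
    return cfg, ds, prior


def rng_seeds(base, n):
    return [int(s) for s in np.random.SeedSequence(base).generate_state(n) % (2**31)]
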