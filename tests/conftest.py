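import numpy as np
import pandas as pd
import pytest

from infoseek.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-timepoint study shared across read-only tests."""
    cfg = GeneratorConfig(n_subjects=16, n_trials=14, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_utilities(small_bundle):
    from infoseek import data_io, utility_construction as uc

    trials = data_io.validate_trials(small_bundle.trials_t1)
    return uc.center_within_participant(uc.build_utilities(trials))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_weights_frame(w, pids=None, timepoint="T1"):
    """Per-subject weights DataFrame from an (n, 3) array."""
    w = np.asarray(w, float)
    if pids is None:
        pids = [f"p{i:03d}" for i in range(len(w))]
    return pd.DataFrame({
        "participant_id": pids,
        "timepoint": timepoint,
        "beta_instrumental": w[:, 0],
        "beta_hedonic": w[:, 1],
        "beta_cognitive": w[:, 2],
        "intercept": 0.0,
    })
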