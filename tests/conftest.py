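import numpy as np
import pandas as pd
import pytest

import symptomap as sm


@pytest.fixture(scope="session")
def worked_fixture():
    """The deterministic 12-sample, 6-feature, 2-output mini-cohort."""
    return sm.make_worked_fixture()


@pytest.fixture(scope="session")
def fitted_fixture_model(worked_fixture):
    """A small model trained on the worked fixture (shared across tests)."""
    X, Y, labels, truth = worked_fixture
    arch = sm.ArchitectureSpec(n_features=X.n_features)
    model = sm.build_model(arch, Y.schema, seed=7)
    hp = sm.Hyperparams(epochs=40, batch_size=4, seed=7)
    return sm.train(model, X, Y, hp)


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["s1", "s2", "s3"],
        columns=["f1", "f2"],
    )
    return sm.OmicsMatrix(df, kind="immune")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort used by several training tests."""
    cfg = sm.SimConfig(
        n_samples=120,
        feature_counts={"immune": 20, "metabolome": 20},
        n_shared_biomarkers=4,
        n_specific_per_output=1,
        effect_size=2.0,
        noise_sd=0.3,
        module_size=2,
        seed=11,
    )
    omics, Y, labels, truth = sm.simulate_cohort(cfg)
    return sm.concatenate_omics(omics), Y, labels, truth
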