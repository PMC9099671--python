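import dataclasses

import numpy as np
import pandas as pd
import pytest

import microguild as mg
from microguild.io import FeatureTable, SampleFrame


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset shared across tests."""
    return mg.generate_dataset(mg.default_params(seed=0))


@pytest.fixture()
def tiny_params():
    """A deliberately small, fast generator configuration."""
    return dataclasses.replace(
        mg.default_params(seed=0),
        mice_per_group=2,
        n_guilds=3,
        members_per_guild=(3, 3),
        n_noise_asvs=6,
        depth=500,
        mu_guild=np.array([2.5, 2.0, 2.0]),
        gamma=np.array([[0.0, 0.0, 0.0], [-0.4, 0.0, 0.4], [0.4, -0.4, 0.0]]),
        delta=np.array([[0.0, 0.5], [0.0, -0.5], [0.0, 0.0]]),
        causal_guilds=(2,),
        causal_betas=(50.0,),
    )


@pytest.fixture()
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3], [0, 7, 2], [4, 4, 4], [1, 0, 9]],
        index=["s1", "s2", "s3", "s4"],
        columns=["a", "b", "c"],
    )
    return FeatureTable(counts)


@pytest.fixture()
def small_frame():
    data = pd.DataFrame(
        {
            "subject_id": ["m1", "m1", "m2", "m2"],
            "group": ["WT", "WT", "KO", "KO"],
            "timepoint": ["w0", "w1", "w0", "w1"],
            "body_weight": [25.0, 30.0, 24.0, 29.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleFrame(data)
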