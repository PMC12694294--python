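import numpy as np
import pandas as pd
import pytest

from fallfusion.config import RunConfig
from fallfusion.extract import build_feature_table
from fallfusion.io import Recording
from fallfusion.simulate import SimConfig, simulate_dataset


def make_recording(n=1024, fs=201.0, label="sitting", rec_id="r0", **channels):
    """Small well-formed recording with overridable channels."""
    t = np.arange(n) / fs
    defaults = dict(
        ax=np.zeros(n), ay=np.zeros(n), az=np.ones(n),
        p=np.full(n, 101.325), T=np.full(n, 20.0),
    )
    defaults.update(channels)
    return Recording(
        recording_id=rec_id, subject_id="s0", dataset_tag="synthetic",
        placement="navel", label=label, fs=fs, t=t, **defaults,
    )


@pytest.fixture(scope="session")
def run_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_dataset(run_config):
    """The default synthetic study mixture (n=600), generated once per session."""
    return simulate_dataset(SimConfig(seed=run_config.seed))


@pytest.fixture(scope="session")
def full_table(default_dataset, run_config):
    """Full feature inventory extracted from the default dataset."""
    return build_feature_table(default_dataset.recordings, run_config)


@pytest.fixture()
def random_table():
    """Feature table of independent random columns (no real redundancy)."""
    rng = np.random.default_rng(42)
    n = 200
    df = pd.DataFrame({f"avm_f{i}": rng.normal(size=n) for i in range(6)})
    df.insert(0, "label", np.where(rng.random(n) < 0.5, "sitting", "falling"))
    df.insert(0, "recording_id", [f"r{i}" for i in range(n)])
    return df
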