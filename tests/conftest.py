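import numpy as np
import pytest

from microvi.data import compute_offsets
from microvi.model import Hyperparameters, build_model_data
from microvi.simulate import ScenarioSpec, simulate_scenario
from microvi.vi import FitOptions, fit, sample_posterior

HYPER = Hyperparameters(k=5, lam=0.5, upsilon=0.5)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated survey with planted modules and known truth."""
    return simulate_scenario(ScenarioSpec(seed=11, n=30, q=15))


@pytest.fixture(scope="session")
def small_model_data(small_dataset):
    ds = small_dataset
    offsets = compute_offsets(ds.table)
    return build_model_data(ds.table, ds.covariates, ds.design, offsets)


@pytest.fixture(scope="session")
def small_fit(small_model_data):
    """A converged fit on the small survey, shared across tests."""
    return fit(
        small_model_data,
        HYPER,
        FitOptions(iters=4000, learning_rate=0.02, seed=7, tol=0.0),
    )


@pytest.fixture(scope="session")
def small_samples(small_fit):
    return sample_posterior(small_fit, 50, 123)


def write_toy_tables(tmp_path, metadata_rows=None):
    """Write an aligned 3-sample TSV trio and return the paths."""
    counts = "sample_id\tt1\tt2\tt3\ns1\t5\t0\t2\ns2\t1\t3\t0\ns3\t0\t2\t8\n"
    covs = "sample_id\tx1\tx2\ns1\t0.5\t1.0\ns2\t-0.5\t2.0\ns3\t0.0\t3.0\n"
    if metadata_rows is None:
        metadata_rows = [
            "s1\tPolar\tSRF\t2010-02-14",
            "s2\tTrades\tMES\t2010-07-01",
            "s3\tCoastal\tDCM\t2011-11-30",
        ]
    meta = "sample_id\tprovince\tdepth_layer\tdate\n" + "\n".join(metadata_rows) + "\n"
    paths = {}
    for name, text in (("counts", counts), ("covariates", covs), ("metadata", meta)):
        p = tmp_path / f"{name}.tsv"
        p.write_text(text)
        paths[name] = p
    return paths
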