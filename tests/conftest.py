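import numpy as np
import pandas as pd
import pytest

import holopred as hp


@pytest.fixture
def worked_counts():
    """The 3-sample x 4-tag count table used as the MRM chain oracle."""
    return pd.DataFrame(
        [[8, 0, 0, 0], [0, 8, 0, 0], [4, 4, 0, 0]],
        index=["S1", "S2", "S3"],
        columns=["t1", "t2", "t3", "t4"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study reused across model tests."""
    cfg = hp.SimConfig(
        n_animals=200, n_snps=150, n_features=200, n_cohorts=4, seed=42
    )
    gt, counts, cohorts, pheno, truth = hp.simulate_dataset(cfg)
    return {
        "cfg": cfg,
        "genotypes": gt,
        "counts": counts,
        "cohorts": cohorts,
        "pheno": pheno,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    gt = small_dataset["genotypes"]
    counts = small_dataset["counts"]
    G = hp.build_grm(gt.dosages)
    M = hp.build_mrm(hp.normalize_l10(hp.log_proportions(counts)))
    return G, M


def rng(seed=0):
    return np.random.default_rng(seed)
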