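import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import hypoxomethyl as hm
from hypoxomethyl import simdata

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured simulated study (fast to generate)."""
    return hm.SimConfig(
        n_patients=3,
        n_benign=2,
        chrom_length_bp=200_000,
        n_cpg=4_000,
        n_planted_hyper=4,
        n_planted_hypo=4,
        n_array_samples=60,
        n_array_decoys=100,
        n_genes=60,
        hypoxia_gene_n=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    samples, truth = simdata.simulate_methylomes(small_config)
    return small_config, samples, truth


def site_frame(pos, diff, p, chrom="chrT"):
    """Per-site test table with the given diff/p tracks."""
    pos = np.asarray(pos)
    diff = np.asarray(diff, float)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "mu1": 0.5 + diff / 2,
            "mu2": 0.5 - diff / 2,
            "diff": diff,
            "se": 0.1,
            "stat": diff / 0.1,
            "p": np.asarray(p, float),
        }
    )
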