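import numpy as np
import pytest

import erconcord as ec


def make_tensor(rising, depth, chrom=None, timepoints=None):
    """Small CountTensor from explicit (S, R, T) arrays."""
    rising = np.asarray(rising)
    depth = np.asarray(depth)
    S, R, T = rising.shape
    if chrom is None:
        chrom = ["2"] * S
    if timepoints is None:
        timepoints = list(range(0, 10 * T, 10))
    alleles = np.empty((S, 2), dtype=object)
    alleles[:, 0] = "A"
    alleles[:, 1] = "T"
    return ec.CountTensor(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.arange(1, S + 1) * 100,
        rising=rising,
        depth=depth,
        alleles=alleles,
        timepoints=np.asarray(timepoints),
        replicates=np.arange(1, R + 1),
    )


@pytest.fixture(scope="session")
def neutral_experiment():
    """Mid-sized fully neutral experiment shared across tests."""
    cfg = ec.SimConfig(
        mode="neutral", n_loci=30_000, census_n=1000, n_replicates=10,
        depth_lambda=80.0, seed=101,
    )
    truth, ct = ec.simulate_experiment(cfg)
    return cfg, truth, ec.polarize_rising(ct)


@pytest.fixture(scope="session")
def selected_experiment():
    """Unlinked experiment with selection targets (winner's-curse design)."""
    cfg = ec.SimConfig(
        mode="unlinked", n_loci=5_000, n_targets=300, p0=0.10, s=0.05,
        census_n=1000, n_replicates=10, depth_lambda=80.0, seed=202,
        generations=(0, 10, 20),
    )
    truth, ct = ec.simulate_experiment(cfg)
    return cfg, truth, ec.polarize_rising(ct)
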