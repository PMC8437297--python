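"""Shared fixtures: small LD references, covariance matrices, and the
three-component mixture fixture used across clustering tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mtgwas.covariance import NullCovariance

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")
from mtgwas.simulate import simulate_ld_panel
from mtgwas.sumstats import SumstatsTable


@pytest.fixture(scope="session")
def ld_small():
    """5 regions x 20 SNPs, AR(1) rho=0.8."""
    return simulate_ld_panel(n_regions=5, snps_per_region=20, ar_rho=0.8, seed=11)


@pytest.fixture(scope="session")
def cov5():
    """A well-conditioned 5-trait null covariance with moderate correlations."""
    rho = np.array([
        [1.0, 0.3, 0.1, 0.0, 0.2],
        [0.3, 1.0, 0.2, 0.1, 0.0],
        [0.1, 0.2, 1.0, 0.3, 0.1],
        [0.0, 0.1, 0.3, 1.0, 0.2],
        [0.2, 0.0, 0.1, 0.2, 1.0]])
    return NullCovariance(rho, method="theoretical")


@pytest.fixture(scope="session")
def mixture_fixture():
    """3 spherical components separated by 10 sigma along every coordinate,
    so assignments stay identifiable when any single coordinate is missing."""
    K = 5
    mu = np.array([[0.0] * K, [10.0] * K, [20.0] * K])
    sigmas = np.array([np.eye(K)] * 3)
    pi = np.array([0.3, 0.4, 0.3])
    return pi, mu, sigmas


def toy_sumstats_df(n=3):
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": "1",
        "pos": np.arange(1, n + 1) * 100,
        "coded_allele": "A",
        "other_allele": "G",
        "beta": np.linspace(-0.2, 0.2, n),
        "se": 0.05,
        "pvalue": np.linspace(0.01, 0.9, n),
        "freq": 0.4,
    })


@pytest.fixture
def toy_table():
    return SumstatsTable(toy_sumstats_df(), trait="toy")
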