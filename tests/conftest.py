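import numpy as np
import pandas as pd
import pytest

from rkpleio.growth import STANDARD_TIMES, logistic
from rkpleio.simulate import EnvironmentSpec, scaled_config
from rkpleio.qtl import GenotypeMatrix
from rkpleio import simulate_cross


@pytest.fixture(scope="session")
def times():
    return STANDARD_TIMES


@pytest.fixture(scope="session")
def small_gm():
    """A small simulated cross: 6 chromosomes x 50 SNPs, ~500 diploids."""
    cfg = scaled_config(500, n_chrom=6, snps_per_chrom=50, seed=42)
    return simulate_cross(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def clean_curve(r, K, N0=1e3, t=STANDARD_TIMES):
    return logistic(t, N0, r, K)


@pytest.fixture(scope="session")
def trait_frame():
    """Deterministic trait table for one environment: K is a noise-free
    downward parabola in r peaking at r = 0.13."""
    rng = np.random.default_rng(7)
    n = 1000
    r = rng.uniform(0.0001, 0.4, n)
    K = 2e6 - 5e7 * (r - 0.13) ** 2
    return pd.DataFrame(
        {
            "environment": "envA",
            "genotype": [f"g{i:04d}" for i in range(n)],
            "r": r,
            "K": K,
            "se_r": 0.001,
            "se_K": 1e4,
            "n_retained": 4,
            "R_g2": 0.99,
        }
    )


def tiny_matrix(codes, chroms=None, positions=None):
    """GenotypeMatrix from a raw (n_snps, n_genotypes) code array."""
    codes = np.asarray(codes, dtype=float)
    n_snps, n_gen = codes.shape
    if chroms is None:
        chroms = np.array(["chr01"] * n_snps, dtype=object)
    if positions is None:
        counters = {}
        positions = []
        for c in chroms:
            counters[c] = counters.get(c, 0) + 1
            positions.append(counters[c] * 100)
        positions = np.array(positions)
    return GenotypeMatrix(
        snp_ids=np.array([f"s{i}" for i in range(n_snps)], dtype=object),
        chromosomes=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions),
        codes=codes,
        genotype_ids=np.array([f"g{j}" for j in range(n_gen)], dtype=object),
    )
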