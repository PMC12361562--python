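import numpy as np
import pandas as pd
import pytest

import flournet as fn
from flournet.correlate import CountrySample
from flournet.items import DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def schema():
    return DEFAULT_SCHEMA


@pytest.fixture(scope="session")
def ref_R():
    """Published total-sample weighted correlation matrix (12x12 ndarray)."""
    return fn.reference.total_sample_correlations().to_numpy()


@pytest.fixture(scope="session")
def ref_N():
    return fn.reference.TOTAL_N


@pytest.fixture(scope="session")
def pooled_omega():
    """Published pooled-network partial correlations (12x12 ndarray)."""
    return fn.reference.pooled_network_matrix().to_numpy()


def random_correlation(p: int, seed: int, strength: float = 1.0) -> np.ndarray:
    """Random PD correlation matrix via a random-factor construction."""
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((p, p + 3)) * strength
    S = W @ W.T + np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def make_sample(
    n: int = 200,
    seed: int = 0,
    missing_rate: float = 0.0,
    corr: np.ndarray | None = None,
    weight_dispersion: float = 0.0,
    country: str = "XX",
) -> CountrySample:
    """Small synthetic country sample for unit tests."""
    cfg = fn.CountryConfig(
        country_code=country,
        n=n,
        missing_rate=missing_rate,
        weight_dispersion=weight_dispersion,
        seed=seed,
    )
    if corr is None:
        corr = random_correlation(12, seed + 1, strength=0.4)
    return fn.generate_country_data(corr, cfg)


@pytest.fixture(scope="session")
def small_study():
    """5 modest countries, tau = 0.08, seeded — shared across tests."""
    configs = [
        fn.CountryConfig(country_code=f"c{i}", n=1200, missing_rate=0.01, seed=300 + i)
        for i in range(5)
    ]
    return fn.generate_study(configs=configs, tau=0.08, seed=42)


@pytest.fixture(scope="session")
def small_cset(small_study):
    cset, _ = fn.build_correlation_set(small_study.samples)
    return cset
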