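import numpy as np
import pytest
from scipy import special

from eqmap.design import CovariateDesign
from eqmap.pipeline import run_benchmark
from eqmap.tariff import load_tariff


@pytest.fixture(scope="session")
def uk_tariff():
    return load_tariff()


def simulate_ordinal(
    n: int,
    beta_eq1,
    beta_eq2,
    k1: float,
    k2: float,
    seed: int,
    n_continuous: int = 1,
    n_binary: int = 1,
):
    """Small ground-truth ordinal sampler used across the PPOM tests.

    Draws ``n_continuous`` standard-normal columns followed by
    ``n_binary`` Bernoulli(0.4) columns and samples d in {1,2,3} from
    the two cumulative-logistic splits. Independent of the package's
    own generator so it can serve as its oracle.
    """
    rng = np.random.default_rng(seed)
    cols = [rng.normal(size=n) for _ in range(n_continuous)]
    cols += [rng.binomial(1, 0.4, size=n).astype(float) for _ in range(n_binary)]
    X = np.column_stack(cols)
    names = tuple(f"x{i + 1}" for i in range(X.shape[1]))
    eta1 = X @ np.asarray(beta_eq1, dtype=float)
    eta2 = X @ np.asarray(beta_eq2, dtype=float)
    c1 = special.expit(k1 - eta1)
    c2 = special.expit(k2 - eta2)
    assert (c2 >= c1).all(), "oracle truth must imply valid probabilities"
    u = rng.random(n)
    d = np.where(u < c1, 1, np.where(u < c2, 2, 3))
    return CovariateDesign(names, X), d


@pytest.fixture(scope="session")
def parallel_fixture():
    """n=3000 draw from a parallel (proportional-odds) truth."""
    return simulate_ordinal(
        3000, beta_eq1=[0.8, -0.5], beta_eq2=[0.8, -0.5], k1=-0.3, k2=1.4, seed=7
    )


#: The default benchmark: all six condition presets at n = 10,000.
BENCHMARK_SEED = 715
BENCHMARK_N = 10_000


@pytest.fixture(scope="session")
def benchmark_results():
    return run_benchmark(n=BENCHMARK_N, seed=BENCHMARK_SEED)
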