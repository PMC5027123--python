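import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_track():
    """A 120-bin diploid-ish track with GC values, counts around 100."""
    from nbcnv.core import BinSet, CountTrack

    r = np.random.default_rng(7)
    n = 120
    bins = BinSet(
        np.array(["chr1"] * n, dtype=object),
        np.arange(n) * 1000,
        (np.arange(n) + 1) * 1000,
        gc=r.uniform(0.3, 0.7, n),
    )
    counts = r.poisson(100, n)
    return CountTrack(bins, counts)


@pytest.fixture(scope="session")
def benchmark_tables():
    """One shared 30-replicate benchmark at the study conditions."""
    from nbcnv.simulate import run_benchmark

    summary, per_rep = run_benchmark(30, seed=1, return_replicates=True)
    return summary, per_rep
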