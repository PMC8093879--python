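import numpy as np
import pytest

import mockbench as mb


@pytest.fixture(scope="session")
def bench_fixture():
    """One shared synthetic benchmark input set (3 species, 2 reference
    strains each, one candidate per ANI bin)."""
    return mb.make_benchmark_fixture(mb.FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def reference_db(bench_fixture):
    return mb.build_reference_db(bench_fixture.records, bench_fixture.ani)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_community(bench_fixture):
    """A tiny simulated community shared by read-level tests."""
    spec = mb.MockCommunitySpec(
        ani_bin="identical",
        diversity_mu=3,
        diversity_sigma=0,
        strain_mode="multiple",
        total_depth_bases=600_000,  # 2,000 pairs
        seed=99,
    )
    return spec, mb.simulate_community(
        spec, bench_fixture.pools["identical"], bench_fixture.sequences
    )
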