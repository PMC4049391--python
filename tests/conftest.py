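import numpy as np
import pytest

from capskit import gelquant, restriction, simulate


@pytest.fixture(scope="session")
def clai():
    return restriction.CLAI


@pytest.fixture(scope="session")
def trio():
    """Default synthetic paralog trio (a: 1968 bp uncut; b/c: 1959 bp cut)."""
    return simulate.make_paralog_set(simulate.ParalogSpec(seed=0))


@pytest.fixture(scope="session")
def trio_patterns(trio, clai):
    return [restriction.digest(v, clai) for v in trio]


@pytest.fixture(scope="session")
def trio_bands(trio_patterns):
    return restriction.classify_bands(trio_patterns, tolerance=0.02)


@pytest.fixture(scope="session")
def trio_incidence(trio_bands, trio):
    return gelquant.build_incidence(trio_bands, trio)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
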