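import warnings

import pytest

from rpfdp.errors import RpfWarning
from rpfdp.synth_bench import SynthConfig, SynthWorld, make_world


@pytest.fixture(autouse=True)
def _quiet_rpf_warnings():
    # placement / clash warnings are expected noise in decoy-heavy tests
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RpfWarning)
        yield


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_residues=14, seed=2)


@pytest.fixture(scope="session")
def small_world(small_config) -> SynthWorld:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RpfWarning)
        return make_world(small_config)


@pytest.fixture(scope="session")
def bench_config() -> SynthConfig:
    return SynthConfig(n_residues=40, seed=17)


@pytest.fixture(scope="session")
def bench_world(bench_config) -> SynthWorld:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RpfWarning)
        return make_world(bench_config)
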