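import numpy as np
import pytest

from tpsmine import blosum62
from tpsmine import fixtures as fx


@pytest.fixture(scope="session")
def scheme():
    return blosum62()


@pytest.fixture(scope="session")
def kit(tmp_path_factory):
    """One synthetic reference kit shared by the whole session."""
    return fx.make_reference_kit(tmp_path_factory.mktemp("kit"), seed=0)


@pytest.fixture(scope="session")
def fixture_genome(tmp_path_factory, kit):
    """Default fixture genome (seed 1) with its structures dir and truth table."""
    out = tmp_path_factory.mktemp("genome1")
    gbk, struct_dir, truth = fx.make_synthetic_genome(fx.FixtureSpec(seed=1), out, kit)
    return gbk, struct_dir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
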