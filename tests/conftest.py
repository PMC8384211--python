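import numpy as np
import pytest

from pscapsid import MoveSet, build_lattice, count_paths


@pytest.fixture(scope="session")
def lattice():
    return build_lattice()


@pytest.fixture(scope="session")
def census_2345(lattice):
    """Enumerated census for the reference move set (64 paths)."""
    return count_paths(lattice, MoveSet([2, 3, 4, 5]), enumerate_paths=True)


@pytest.fixture(scope="session")
def fast_kinetics():
    """Short-horizon kinetics for cheap simulation tests."""
    from pscapsid import KineticParams

    return KineticParams(t_max=2.0e5, quiesce_window=5.0e4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
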