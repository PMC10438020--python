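import numpy as np
import pytest

import caedec as cd


@pytest.fixture(scope="session")
def small_survey():
    """300-record, well-separated 3-cluster survey with truth labels."""
    spec = cd.default_mixture(n=300, separation=4.0, seed=7)
    return cd.simulate_survey(spec)


@pytest.fixture(scope="session")
def small_features(small_survey):
    table, truth = small_survey
    return cd.encode_features(table), truth


@pytest.fixture(scope="session")
def grid_2x2():
    """2x2 checkerboard lattice: values (+1, -1, -1, +1) row-major."""
    return cd.simulate_lattice(cd.LatticeSpec(2, 2, "checkerboard", contrast=1.0))


@pytest.fixture(scope="session")
def grid_4x4_blocks():
    """4x4 lattice, left half ~0 / right half ~10 (two vertical bands)."""
    return cd.simulate_lattice(
        cd.LatticeSpec(4, 4, "block", n_blocks=2, contrast=10.0, noise_sd=0.1, seed=3)
    )


def random_lattice(n_side: int, seed: int):
    return cd.simulate_lattice(cd.LatticeSpec(n_side, n_side, "iid", seed=seed))
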