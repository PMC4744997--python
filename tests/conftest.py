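import numpy as np
import pytest

from nichescheme.trait_data import TraitMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tm():
    """3 species x 2 traits, hand-checkable."""
    return TraitMatrix(
        "habitat",
        ("sp_a", "sp_b", "sp_c"),
        ("depth", "velocity"),
        np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 9.0]]),
    )


@pytest.fixture
def random_tm(rng):
    """10 species x 4 traits of plain Gaussian noise."""
    return TraitMatrix(
        "trophic",
        tuple(f"sp{i:02d}" for i in range(10)),
        ("t1", "t2", "t3", "t4"),
        rng.normal(0, 3, (10, 4)) + rng.normal(0, 1, (1, 4)),
    )


def make_clustered_tm(seed, n=45, n_groups=3, n_traits=8, separation=6.0,
                      dimension="habitat"):
    """Trait block with species clustered around separated peaks."""
    from nichescheme.synthetic import _group_labels, _peak_positions

    rng = np.random.default_rng(seed)
    labels = _group_labels(rng, n, n_groups)
    peaks = _peak_positions(rng, n_groups, n_traits, separation)
    vals = peaks[labels] + rng.normal(0, 1, (n, n_traits))
    tm = TraitMatrix(
        dimension,
        tuple(f"sp{i:03d}" for i in range(n)),
        tuple(f"{dimension}_t{j}" for j in range(n_traits)),
        vals,
    )
    return tm, labels + 1
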