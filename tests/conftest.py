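import numpy as np
import pytest

from mucomap import phantom as ph


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Single z-aligned cylinder, radius 12, length 100, in a 128^3 volume."""
    branch = ph.Branch(1, None, (10, 64, 64), (1, 0, 0), 100, 12, 1, "LL")
    return ph.build_tree_volume(ph.TreeSpec((branch,)), (128, 128, 128), 1.0)


@pytest.fixture(scope="session")
def tilted_phantom():
    """45-degree tilted cylinder, radius 12, length 120."""
    s2 = 1 / np.sqrt(2)
    branch = ph.Branch(1, None, (14, 14, 64), (s2, s2, 0), 120, 12, 1, "LL")
    return ph.build_tree_volume(ph.TreeSpec((branch,)), (128, 128, 128), 1.0)


@pytest.fixture(scope="session")
def two_branch_phantom():
    """Monopodial tree: trunk plus one 45-degree child, with a plug."""
    s2 = 1 / np.sqrt(2)
    spec = ph.TreeSpec(
        (
            ph.Branch(1, None, (8, 60, 60), (1, 0, 0), 110, 12, 1, "LL"),
            ph.Branch(2, 1, (58, 60, 60), (s2, s2, 0), 50, 8, 2, "LL"),
        )
    )
    built = ph.build_tree_volume(spec, (128, 128, 128), 1.0)
    mucus, truth = ph.carve_mucus(
        built, [ph.Deposit(1, (0.2, 0.5), "plug", fill_fraction=1.0)]
    )
    return built, mucus, truth


def digital_disc_count(radius: float, size: int = 64) -> int:
    """Brute-force count of grid points with centre strictly inside radius."""
    c = size // 2
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return int(np.sum((yy - c) ** 2 + (xx - c) ** 2 < radius**2))
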