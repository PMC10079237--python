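import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wpcf.pointcloud import Domain, LabelledPointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cloud():
    """A hand-built 6-point cloud with all five categories and two marks."""
    domain = Domain(0.0, 10.0, 0.0, 8.0)
    return LabelledPointCloud(
        positions=[[1, 1], [2, 2], [3, 3], [4, 4], [5, 5], [9, 7]],
        categories=["B", "M", "M", "S", "T", "N"],
        marks=[np.nan, 0.25, 0.8, np.nan, np.nan, np.nan],
        domain=domain,
    )


def random_cloud(rng, n=20, boundary_mode="clipped", width=4.0, height=3.0):
    """A random labelled cloud with marks on macrophages."""
    domain = Domain(0.0, width, 0.0, height, boundary_mode=boundary_mode)
    positions = np.column_stack(
        [rng.uniform(0, width, n), rng.uniform(0, height, n)]
    )
    categories = rng.choice(list("BMSTN"), n)
    marks = np.where(categories == "M", rng.uniform(0, 1, n), np.nan)
    return LabelledPointCloud(positions, categories, marks, domain)
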