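import numpy as np
import pytest

from spikekit.geometry import OrientedBox, normalize_box


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


def random_box(rng, center_range=(0.0, 120.0), side_range=(5.0, 100.0)) -> OrientedBox:
    """A random normalized box; default ranges make overlaps common in pairs."""
    return normalize_box(
        OrientedBox(
            rng.uniform(*center_range),
            rng.uniform(*center_range),
            rng.uniform(*side_range),
            rng.uniform(*side_range),
            rng.uniform(0.0, 180.0),
        )
    )
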