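import numpy as np
import pytest

from azocyd.geometry import AxisFrame, Structure


@pytest.fixture
def z_frame() -> AxisFrame:
    return AxisFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))


def make_bead(label: str, xyz, charge=0.0, sigma=0.3, eps=0.2) -> Structure:
    return Structure(
        labels=[label],
        coords=np.array([xyz], dtype=float),
        charges=np.array([charge]),
        lj_sigma=np.array([sigma]),
        lj_epsilon=np.array([eps]),
    )


@pytest.fixture
def bead_pair():
    """Two neutral single-bead structures for LJ checks."""
    a = make_bead("A", (0.0, 0.0, 0.0))
    b = make_bead("B", (0.0, 0.0, 0.3 * 2 ** (1 / 6)))
    return a, b
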