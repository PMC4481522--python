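import numpy as np
import pytest

from valvemorph.imageprep import BinaryMask, SkeletonMask


def as_skeleton(mask: np.ndarray, pixel_size_um: float = 1.0) -> SkeletonMask:
    return SkeletonMask(mask.astype(bool), pixel_size_um, provenance=[{"op": "fixture"}])


def as_mask(mask: np.ndarray, pixel_size_um: float = 1.0) -> BinaryMask:
    return BinaryMask(mask.astype(bool), pixel_size_um, provenance=[{"op": "fixture"}])


@pytest.fixture
def y_skeleton() -> SkeletonMask:
    """One junction at (20,20) with three 10-px orthogonal arms."""
    m = np.zeros((40, 40), bool)
    m[10:20, 20] = True  # north arm
    m[20, 10:20] = True  # west arm
    m[20, 21:31] = True  # east arm
    m[20, 20] = True  # the junction pixel
    return as_skeleton(m)


@pytest.fixture
def line_skeleton() -> SkeletonMask:
    """A straight horizontal 50-px filament: no junctions at all."""
    m = np.zeros((20, 60), bool)
    m[10, 5:55] = True
    return as_skeleton(m)


@pytest.fixture
def lattice_skeleton() -> SkeletonMask:
    """A 4x4-vertex square lattice (3x3 cells of 6x6 interior px)."""
    m = np.zeros((30, 30), bool)
    for k in (0, 7, 14, 21):
        m[4 + k, 4 : 4 + 22] = True
        m[4 : 4 + 22, 4 + k] = True
    return as_skeleton(m)


@pytest.fixture
def square_outline_skeleton() -> SkeletonMask:
    """A 20x20 square outline enclosing an 18x18 interior."""
    m = np.zeros((30, 30), bool)
    m[5:25, 5] = True
    m[5:25, 24] = True
    m[5, 5:25] = True
    m[24, 5:25] = True
    return as_skeleton(m)


@pytest.fixture
def theta_skeleton(square_outline_skeleton) -> SkeletonMask:
    """Square outline plus a horizontal chord: a theta shape, two meshes."""
    m = square_outline_skeleton.pixels.copy()
    m[14, 5:25] = True
    return as_skeleton(m)
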