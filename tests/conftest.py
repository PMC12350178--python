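import numpy as np
import pytest
from scipy import ndimage

from hepmorph.ect import GridSpec, sect_from_polygon
from hepmorph.synthetic import ShapeSpec, gen_outline


def euler_label_oracle(mask: np.ndarray) -> int:
    """Independent chi oracle: 8-connected components minus 4-connected
    enclosed holes of a 2D binary mask."""
    mask = np.asarray(mask, bool)
    n_comp = ndimage.label(mask, structure=np.ones((3, 3)))[1]
    bg = np.pad(~mask, 1, constant_values=True)
    lbl, n_bg = ndimage.label(bg, structure=ndimage.generate_binary_structure(2, 1))
    border_labels = set(np.unique(
        np.concatenate([lbl[0], lbl[-1], lbl[:, 0], lbl[:, -1]])
    )) - {0}
    holes = n_bg - len(border_labels)
    return n_comp - holes


@pytest.fixture(scope="session")
def disc_outline():
    return gen_outline(ShapeSpec(family="ball", noise=0.0, seed=1))


@pytest.fixture(scope="session")
def grape_outline():
    return gen_outline(ShapeSpec(family="grape", noise=0.0, seed=2))


@pytest.fixture(scope="session")
def random_shapes():
    """Ten varied noisy shapes on a shared grid, with their descriptors."""
    specs = [
        ShapeSpec(family="ball" if i % 2 else "grape", lobes=3 + i % 4,
                  amplitude=0.1 + 0.05 * (i % 5), noise=0.01, seed=100 + i)
        for i in range(10)
    ]
    polys = [gen_outline(s) for s in specs]
    grid = GridSpec.for_polygons(polys)
    descs = [sect_from_polygon(p, grid=grid) for p in polys]
    return polys, grid, descs
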