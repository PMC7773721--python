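import dendropy
import numpy as np
import pytest

import beehex as bh


@pytest.fixture(scope="session")
def grid():
    return bh.DEFAULT_GRID


@pytest.fixture(scope="session")
def leaf_background(grid):
    leaves = [bh.gen_leaf_spectrum(10_000 + i, grid=grid) for i in range(10)]
    return bh.mean_background(leaves)


@pytest.fixture(scope="session")
def sensitivities(grid):
    return bh.bee_sensitivities(grid=grid)


@pytest.fixture(scope="session")
def illuminant(grid):
    return bh.d65_photon_flux(grid=grid)


@pytest.fixture(scope="session")
def to_locus(leaf_background, sensitivities, illuminant):
    """Shortcut: spectrum -> hexagon locus against the standard setup."""

    def _convert(spectrum):
        return bh.spectrum_to_locus(spectrum, leaf_background, sensitivities, illuminant)

    return _convert


@pytest.fixture
def balanced_four_tip_tree():
    """Ultrametric depth-3 balanced tree: ((a:1,b:1):2,(c:2,d:2):1);"""
    return dendropy.Tree.get(
        data="((a:1,b:1):2,(c:2,d:2):1);", schema="newick", preserve_underscores=True
    )


@pytest.fixture
def star_tree():
    return dendropy.Tree.get(
        data="(a:1.5,b:1.5,c:1.5,d:1.5,e:1.5);", schema="newick", preserve_underscores=True
    )


def random_loci(n, seed, scale=0.4):
    """Helper: n random chromatic loci inside the hexagon."""
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-scale, scale, size=(n, 2))
    loci = []
    for i, (x, y) in enumerate(pts):
        r = float(np.hypot(x, y))
        theta = float(np.degrees(np.arctan2(y, x)) % 360.0)
        loci.append(bh.ColorLocus(f"sp{i}", float(x), float(y), theta if r else 0.0, r,
                                  bh.colorspace.sector_of(theta) if r else None))
    return loci
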