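import anndata as ad
import numpy as np
import pandas as pd
import pytest

import beadcomp as bc


@pytest.fixture(scope="session")
def small_reference():
    """Labelled single-cell reference: 3 types, 60 genes."""
    return bc.make_reference(3, 60, 40, depth=800, seed=1)


@pytest.fixture(scope="session")
def layered_puck(small_reference):
    """Single puck with two pure layers and its ground truth."""
    spec = bc.TissueSpec(
        n_pucks=1, puck_extent=(1000, 800), bead_spacing=50,
        layers=[bc.LayerSpec((0, 400), {"type0": 1.0}),
                bc.LayerSpec((400, 800), {"type1": 1.0})],
        depth=500, seed=2)
    return bc.make_layered_puck(spec, small_reference)


def grid_beads(nx, ny, spacing=20.0, n_pucks=1, prefix="b"):
    """Bare bead AnnData on a grid (unit counts), for spatial statistics."""
    n = nx * ny
    coords = np.column_stack([np.repeat(np.arange(nx) * spacing, ny),
                              np.tile(np.arange(ny) * spacing, nx)])
    blocks, names, pucks = [], [], []
    for p in range(n_pucks):
        blocks.append(coords)
        names += [f"{prefix}{p}_{i:04d}" for i in range(n)]
        pucks += [f"puck{p}"] * n
    beads = ad.AnnData(X=np.ones((n * n_pucks, 2)),
                       obs=pd.DataFrame({"puck": pucks}, index=names),
                       var=pd.DataFrame(index=["g1", "g2"]))
    beads.obsm["spatial"] = np.vstack(blocks)
    return beads


@pytest.fixture
def line_beads():
    """21 beads on a line at x = 0, 100, ..., 2000 µm."""
    beads = grid_beads(21, 1, spacing=100.0)
    return beads
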