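import numpy as np
import pytest

from bandnet import BoldMatrix, MultiGraph, VoxelGraph
from bandnet.network import scan_order_coords


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_bold(rng, n_voxels=12, n_timepoints=64, tr=2.0):
    values = rng.normal(size=(n_voxels, n_timepoints))
    return BoldMatrix(
        values=values, tr_seconds=tr, voxel_coords=scan_order_coords(n_voxels)
    )


def random_voxel_graph(rng, n=15, p=0.3, band_label=""):
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return VoxelGraph(
        n_vertices=n,
        vertex_coords=scan_order_coords(n),
        edges=frozenset(edges),
        band_label=band_label,
    )


def random_multigraph(rng, n=15, p=0.3, bands=("low", "intermediate", "high", "full")):
    mg = MultiGraph(n_vertices=n, vertex_coords=scan_order_coords(n))
    for b in bands:
        mg.edge_sets[b] = random_voxel_graph(rng, n, p).edges
    return mg


@pytest.fixture
def small_multigraph(rng):
    return random_multigraph(rng)
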