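import numpy as np
import pytest

from tomo3d.io import Mask3D, TomoSeqDataset
from tomo3d.maskgen import ShapeSpec, make_ellipsoid_mask


@pytest.fixture
def small_mask() -> Mask3D:
    """A 6x5x4 mask with an irregular but non-degenerate support."""
    rng = np.random.default_rng(42)
    values = (rng.random((6, 5, 4)) < 0.6).astype(np.uint8)
    values[0, 0, 0] = 1  # guarantee non-empty
    return Mask3D(values)


@pytest.fixture
def ellipsoid_20() -> Mask3D:
    return make_ellipsoid_mask(ShapeSpec(
        kind="ellipsoid", shape=(20, 20, 20), radii=(9, 8, 7)))


def random_dataset(rng, n_genes=8, shape=(6, 5, 4),
                   n_zero_rows=0) -> TomoSeqDataset:
    """Random nonnegative dataset; optionally with all-zero gene rows."""
    lx, ly, lz = shape
    X = rng.integers(0, 50, size=(n_genes, lx)).astype(float)
    Y = rng.integers(0, 50, size=(n_genes, ly)).astype(float)
    Z = rng.integers(0, 50, size=(n_genes, lz)).astype(float)
    for m, g in zip((X, Y, Z), range(n_zero_rows)):
        m[g] = 0.0
    # keep at least one positive entry per column for most genes
    X[-1] += 1; Y[-1] += 1; Z[-1] += 1
    return TomoSeqDataset(gene_ids=[f"g{i}" for i in range(n_genes)],
                          X=X, Y=Y, Z=Z)


@pytest.fixture
def dataset_small() -> TomoSeqDataset:
    return random_dataset(np.random.default_rng(7))
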