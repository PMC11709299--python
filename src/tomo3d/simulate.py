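"""Synthetic tomo-seq data with known 3D ground truth.

The simulated sample is an ellipsoid voxelized on a 50 x 50 x 50 grid and
sectioned 50 times along each of the three orthogonal axes (x: anterior-
posterior, y: ventral-dorsal, z: left-right).  Five spatial genes carry
regionalized patterns (a centered blob, the same blob over a weak
ubiquitous background, an anterior spot, a left-right mirrored spot pair,
and a spot offset from both the left-right and dorsal-ventral mid-planes);
background genes carry spatially unstructured RNA-seq-like counts, drawn
per voxel from a negative binomial whose per-gene mean follows a
log-normal across genes.  Each gene's three 1D profiles are the exact
marginal sums of its 3D truth volume, so the reconstruction problem is
feasible by construction and accuracy can be scored against the truth.

Seeding is counter-based: one base seed expands to independent per-
(replicate, gene) streams, so adding genes or replicates never reshuffles
existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Mask3D, TomoSeqDataset
from .maskgen import ShapeSpec, make_ellipsoid_mask

DEFAULT_GRID = (50, 50, 50)
DEFAULT_MASK_RADII = (24.0, 18.0, 14.0)
SIM_AXIS_LABELS = ("AP", "VD", "LR")


@dataclass
class PatternSpec:
    """A spatial gene's expression pattern: strong regions over a floor.

    The truth volume is ``high_level`` inside the union of the regions
    (intersected with the mask), ``low_level`` elsewhere inside the mask,
    and 0 outside.  Each region is an ellipsoid given as (center, radii)
    in voxel units.
    """

    name: str
    high_level: float
    low_level: float
    regions: list[tuple[tuple[float, float, float],
                        tuple[float, float, float]]]

    def __post_init__(self):
        if not self.high_level > self.low_level >= 0:
            raise ValueError("need high_level > low_level >= 0")
        if not self.regions:
            raise ValueError("pattern needs at least one region")


@dataclass
class BackgroundModel:
    """Count model for spatially unstructured background genes.

    Per gene, a mean expression level is drawn from a log-normal
    (``log_mean``, ``log_sd`` on the log scale); per voxel inside the mask,
    counts are negative binomial with that mean and size parameter
    ``dispersion`` (variance = mu + mu^2/dispersion, so small values mean
    strong overdispersion and the Poisson limit is dispersion -> inf).
    """

    log_mean: float = 1.0
    log_sd: float = 1.0
    dispersion: float = 0.5

    def __post_init__(self):
        if self.log_sd < 0 or self.dispersion <= 0:
            raise ValueError("log_sd must be >= 0 and dispersion > 0")


@dataclass
class SimulationTruth:
    """One simulated replicate: mask, spatial-gene truths, and the dataset."""

    mask: Mask3D
    truth_volumes: dict[str, np.ndarray]
    dataset: TomoSeqDataset
    seed: int
    replicate_index: int
    background_model: BackgroundModel
    patterns: list[PatternSpec] = field(default_factory=list)


def default_mask(grid: tuple[int, int, int] = DEFAULT_GRID,
                 radii: tuple[float, float, float] = DEFAULT_MASK_RADII,
                 ) -> Mask3D:
    """The standard simulated sample: a centered ellipsoid."""
    return make_ellipsoid_mask(ShapeSpec(
        kind="ellipsoid", shape=grid, radii=radii,
        axis_labels=SIM_AXIS_LABELS))


def default_patterns(grid: tuple[int, int, int] = DEFAULT_GRID,
                     mask_radii: tuple[float, float, float] = DEFAULT_MASK_RADII,
                     high_level: float = 100.0,
                     ) -> list[PatternSpec]:
    """The five standard spatial gene patterns.

    Gene1/Gene2: centered ellipsoid at 40% of the mask radii (Gene2 adds a
    ubiquitous floor at 40% of the high level).  Gene3: a radius-4 spot at
    the anterior pole region (70% of the way to the anterior tip).  Gene4:
    two radius-4 anterior spots mirrored across the left-right mid-plane.
    Gene5: a radius-4 spot offset 8 voxels from both the left-right and
    dorsal-ventral mid-planes.
    """
    cx, cy, cz = (g / 2 for g in grid)
    rx, ry, rz = mask_radii
    center = (cx, cy, cz)
    blob_radii = tuple(0.4 * r for r in mask_radii)
    spot = (4.0, 4.0, 4.0)
    anterior_x = cx - 0.7 * rx
    return [
        PatternSpec("Gene1", high_level, 0.0, [(center, blob_radii)]),
        PatternSpec("Gene2", high_level, 0.4 * high_level,
                    [(center, blob_radii)]),
        PatternSpec("Gene3", high_level, 0.0,
                    [((anterior_x, cy, cz), spot)]),
        PatternSpec("Gene4", high_level, 0.0,
                    [((anterior_x, cy, cz - 8.0), spot),
                     ((anterior_x, cy, cz + 8.0), spot)]),
        PatternSpec("Gene5", high_level, 0.0,
                    [((cx, cy + 8.0, cz + 8.0), spot)]),
    ]


def make_spatial_truth(pattern: PatternSpec, mask: Mask3D) -> np.ndarray:
    """Render a pattern into a truth volume on the mask support."""
    grids = np.meshgrid(*(np.arange(s) + 0.5 for s in mask.shape),
                        indexing="ij")
    in_region = np.zeros(mask.shape, dtype=bool)
    for center, radii in pattern.regions:
        q = sum(((g - c) / r) ** 2
                for g, c, r in zip(grids, center, radii))
        in_region |= q <= 1.0
    support = mask.values.astype(bool)
    if not (in_region & support).any():
        raise ValueError(
            f"pattern {pattern.name!r}: no region voxel inside the mask")
    E = np.where(support, pattern.low_level, 0.0)
    E[in_region & support] = pattern.high_level
    return E


def _gene_rng(seed: int, replicate: int, gene_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(replicate, gene_index))
    return np.random.default_rng(ss)


def _background_counts(rng: np.random.Generator, n_voxels: int,
                       model: BackgroundModel) -> np.ndarray:
    mu = rng.lognormal(model.log_mean, model.log_sd)
    r = model.dispersion
    return rng.negative_binomial(r, r / (r + mu), size=n_voxels).astype(float)


def make_background_truth(n_genes: int, mask: Mask3D,
                          model: BackgroundModel | None = None,
                          seed: int = 0, replicate: int = 0,
                          ) -> dict[str, np.ndarray]:
    """Full 3D truth volumes for background genes (small n only: one
    50-cubed float volume per gene)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    model = model or BackgroundModel()
    support = mask.values.astype(bool)
    n_vox = mask.n_voxels
    volumes = {}
    for g in range(n_genes):
        E = np.zeros(mask.shape)
        E[support] = _background_counts(_gene_rng(seed, replicate, g),
                                        n_vox, model)
        volumes[_bg_name(g, n_genes)] = E
    return volumes


def _bg_name(index: int, n_genes: int) -> str:
    width = max(4, len(str(n_genes)))
    return f"bg{index + 1:0{width}d}"


def marginalize_volume(E: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A volume's three 1D section profiles: sums over the other two axes."""
    E = np.asarray(E)
    if np.any(E < 0):
        raise ValueError("volume must be nonnegative")
    return E.sum(axis=(1, 2)), E.sum(axis=(0, 2)), E.sum(axis=(0, 1))


def simulate_tomoseq(n_background: int = 1997,
                     patterns: list[PatternSpec] | None = None,
                     replicate: int = 0,
                     seed: int = 0,
                     mask: Mask3D | None = None,
                     background_model: BackgroundModel | None = None,
                     ) -> SimulationTruth:
    """Generate one simulated tomo-seq replicate.

    Spatial truths are deterministic; background counts depend on
    (seed, replicate).  Background marginals are accumulated per gene
    without materializing each 50-cubed volume, using the same per-gene
    streams as :func:`make_background_truth`, so the two paths agree
    draw for draw.
    """
    mask = mask or default_mask()
    patterns = default_patterns() if patterns is None else patterns
    model = background_model or BackgroundModel()

    truth_volumes: dict[str, np.ndarray] = {}
    gene_ids: list[str] = []
    xs, ys, zs = [], [], []
    for pattern in patterns:
        E = make_spatial_truth(pattern, mask)
        truth_volumes[pattern.name] = E
        gene_ids.append(pattern.name)
        x, y, z = marginalize_volume(E)
        xs.append(x); ys.append(y); zs.append(z)

    # background genes: bincount the mask-voxel draws straight into marginals
    ix, iy, iz = np.nonzero(mask.values)
    lx, ly, lz = mask.shape
    n_vox = ix.size
    for g in range(n_background):
        vals = _background_counts(_gene_rng(seed, replicate, g), n_vox, model)
        gene_ids.append(_bg_name(g, n_background))
        xs.append(np.bincount(ix, weights=vals, minlength=lx))
        ys.append(np.bincount(iy, weights=vals, minlength=ly))
        zs.append(np.bincount(iz, weights=vals, minlength=lz))

    dataset = TomoSeqDataset(gene_ids=gene_ids, X=np.array(xs),
                             Y=np.array(ys), Z=np.array(zs),
                             axis_labels=mask.axis_labels)
    return SimulationTruth(mask=mask, truth_volumes=truth_volumes,
                           dataset=dataset, seed=seed,
                           replicate_index=replicate,
                           background_model=model, patterns=patterns)
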