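"""Two-stage normalization of raw tomo-seq matrices before reconstruction.

Stage 1 (inter-section normalization) corrects for unequal sequencing
depth and unequal material volume across sections: each count is divided
by its section's total expression over all genes and multiplied by the
section's relative material volume, measured as the number of mask voxels
in that section.  Stage 2 (common scaling) rescales the three per-gene
axis vectors to a shared total T, the grand total of the raw matrices
averaged over the three axes, so that the three marginals the fitter must
match are mutually consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import Mask3D, TomoSeqDataset

logger = logging.getLogger(__name__)


@dataclass
class MaskMarginals:
    """Per-section mask voxel counts: relative material volume per section."""

    m_x: np.ndarray
    m_y: np.ndarray
    m_z: np.ndarray

    def __post_init__(self):
        self.m_x = np.asarray(self.m_x, dtype=float)
        self.m_y = np.asarray(self.m_y, dtype=float)
        self.m_z = np.asarray(self.m_z, dtype=float)
        totals = {self.m_x.sum(), self.m_y.sum(), self.m_z.sum()}
        if len({round(t, 6) for t in totals}) != 1:
            raise ValueError("marginal vectors disagree on total voxel count")


@dataclass
class NormalizedGeneVectors:
    """Preprocessed per-gene axis vectors, each summing to the common total T.

    An axis whose vector is all zero (gene undetected along that axis)
    leaves the gene flagged non-reconstructable; the fitter refuses it.
    """

    gene_id: str
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    T: float
    reconstructable: bool = True
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        for label, v in zip("xyz", (self.x, self.y, self.z)):
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{label} vector must be finite and >= 0")


def compute_mask_marginals(mask: Mask3D) -> MaskMarginals:
    """Sum the mask over two axes at a time: voxel count per section."""
    m = mask.values.astype(float)
    return MaskMarginals(
        m_x=m.sum(axis=(1, 2)),
        m_y=m.sum(axis=(0, 2)),
        m_z=m.sum(axis=(0, 1)),
    )


def _normalize_axis(mat: np.ndarray, m: np.ndarray, axis_name: str,
                    warnings: list[str]) -> np.ndarray:
    colsum = mat.sum(axis=0)
    out = np.zeros_like(mat, dtype=float)
    ok = colsum > 0
    out[:, ok] = mat[:, ok] * (m[ok] / colsum[ok])
    n_empty = int((~ok).sum())
    if n_empty:
        msg = (f"{axis_name}: {n_empty} section(s) with zero total expression; "
               "normalized values set to 0")
        warnings.append(msg)
        logger.warning(msg)
    return out


def intersection_normalize(dataset: TomoSeqDataset,
                           marginals: MaskMarginals) -> TomoSeqDataset:
    """Inter-section normalization: counts -> per-volume relative expression.

    Entry (g, i) becomes ``X[g, i] * m_x[i] / sum_h X[h, i]``; a section
    with zero total expression carries no allocable signal and maps to 0
    with a warning.  After this stage each section's column total equals
    the section's mask voxel count wherever the raw total was positive.
    """
    if "intersection" in dataset.normalized:
        raise ValueError("dataset already intersection-normalized; "
                         "refusing to apply the stage twice")
    shapes = dataset.shape3d
    msizes = (marginals.m_x.size, marginals.m_y.size, marginals.m_z.size)
    if shapes != msizes:
        raise ValueError(
            f"dataset sections {shapes} do not match mask marginals {msizes}")
    warnings: list[str] = []
    return TomoSeqDataset(
        gene_ids=list(dataset.gene_ids),
        X=_normalize_axis(dataset.X, marginals.m_x, "x", warnings),
        Y=_normalize_axis(dataset.Y, marginals.m_y, "y", warnings),
        Z=_normalize_axis(dataset.Z, marginals.m_z, "z", warnings),
        axis_labels=dataset.axis_labels,
        normalized=dataset.normalized + ("intersection",),
    )


def common_total(dataset_raw: TomoSeqDataset) -> float:
    """T: the grand totals of the three raw matrices, averaged."""
    return float(dataset_raw.X.sum() + dataset_raw.Y.sum()
                 + dataset_raw.Z.sum()) / 3.0


def common_scale(dataset_raw: TomoSeqDataset,
                 dataset_normalized: TomoSeqDataset,
                 gene_id: str) -> NormalizedGeneVectors:
    """Rescale one gene's (normalized) axis vectors to the common total T.

    T comes from the raw matrices; each normalized vector is divided by its
    own sum and multiplied by T, so the three axis totals agree exactly.
    An all-zero vector on any axis stays zero and flags the gene
    non-reconstructable.
    """
    T = common_total(dataset_raw)
    x, y, z = dataset_normalized.gene_vectors(gene_id)
    out = []
    reconstructable = True
    notes: list[str] = []
    for label, v in zip("xyz", (x, y, z)):
        s = v.sum()
        if s > 0:
            out.append(v * (T / s))
        else:
            out.append(np.zeros_like(v, dtype=float))
            reconstructable = False
            notes.append(f"axis {label}: zero row sum; gene not reconstructable")
    return NormalizedGeneVectors(gene_id=gene_id, x=out[0], y=out[1], z=out[2],
                                 T=T, reconstructable=reconstructable,
                                 notes=notes)


def preprocess_gene(dataset: TomoSeqDataset, mask: Mask3D, gene_id: str,
                    normalize: bool = True) -> NormalizedGeneVectors:
    """Full preprocessing chain for one gene.

    With ``normalize`` on, applies inter-section normalization then common
    scaling; with it off, skips the inter-section stage but still applies
    common scaling so the three axis totals agree (the fitter requires it).
    """
    if normalize:
        marginals = compute_mask_marginals(mask)
        normalized = intersection_normalize(dataset, marginals)
    else:
        normalized = dataset
    return common_scale(dataset, normalized, gene_id)
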