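"""Masked iterative proportional fitting (IPF) of 3D expression volumes.

Given one gene's preprocessed section profiles along three orthogonal axes
and a binary support mask, IPF starts from the mask itself and cyclically
rescales each axis's slices so that the volume's marginal along that axis
matches the gene's profile.  Because updates are multiplicative, voxels
outside the mask stay exactly zero at every iteration.  One "set" fits the
x, y, then z axis, in that fixed order; after the final z step the
z-marginal matches exactly and the total mass equals the common total T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Mask3D, Reconstruction3D, TomoSeqDataset
from .preprocess import (NormalizedGeneVectors, compute_mask_marginals,
                         common_scale, intersection_normalize)

logger = logging.getLogger(__name__)

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class IPFConfig:
    """Fitting parameters.

    iterations: number of axis-cycle sets m; exactly m sets are run (no
    early stopping), matching a fixed predetermined iteration count.
    loss_every: record the loss after every loss_every-th set.
    epsilon_denominator: slice sums at or below this are treated as zero;
    0 (exact test) is safe because all values are nonnegative.
    """

    iterations: int = 100
    loss_every: int = 1
    epsilon_denominator: float = 0.0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.loss_every < 1:
            raise ValueError("loss_every must be >= 1")
        if self.epsilon_denominator < 0:
            raise ValueError("epsilon_denominator must be >= 0")


def ipf_step_axis(values: np.ndarray, marginal: np.ndarray, axis: str | int,
                  epsilon: float = 0.0,
                  ) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """One marginal-fitting step along one axis.

    Each slice i (the 2D cross-section at index i of the axis) is scaled by
    ``marginal[i] / slice_sum`` so its sum becomes ``marginal[i]``.  A slice
    whose current sum is <= epsilon cannot absorb mass: it is left as-is
    (zeros) and its target mass is reported as unassignable.  A zero target
    zeroes the slice.  Returns the updated array and a list of
    (slice index, unassignable mass) pairs.
    """
    ax = _AXIS_INDEX.get(axis, axis)
    marginal = np.asarray(marginal, dtype=float)
    if marginal.size != values.shape[ax]:
        raise ValueError(
            f"marginal length {marginal.size} != axis extent {values.shape[ax]}")
    if np.any(marginal < 0):
        raise ValueError("marginal contains negative entries")
    sum_axes = tuple(d for d in range(3) if d != ax)
    slice_sums = values.sum(axis=sum_axes)
    factor = np.ones_like(marginal)
    ok = slice_sums > epsilon
    factor[ok] = marginal[ok] / slice_sums[ok]
    # a positive target on an empty slice stays unassigned (slice is all zero)
    degenerate = ~ok & (marginal > 0)
    factor[~ok & (marginal == 0)] = 0.0
    shape = [1, 1, 1]
    shape[ax] = marginal.size
    updated = values * factor.reshape(shape)
    unassigned = [(int(i), float(marginal[i])) for i in np.nonzero(degenerate)[0]]
    return updated, unassigned


def ipf_loss(values: np.ndarray, vectors: NormalizedGeneVectors) -> float:
    """Sum of squared marginal residuals over the three axes."""
    rx = values.sum(axis=(1, 2)) - vectors.x
    ry = values.sum(axis=(0, 2)) - vectors.y
    rz = values.sum(axis=(0, 1)) - vectors.z
    return float(rx @ rx + ry @ ry + rz @ rz)


def ipf_fit(vectors: NormalizedGeneVectors, mask: Mask3D,
            config: IPFConfig | None = None) -> Reconstruction3D:
    """Fit a 3D volume to three axis profiles under the mask support.

    The initial volume is the binary mask itself; the first x-step then
    sets the overall scale.  Runs exactly ``config.iterations`` sets of
    x, y, z steps and records the loss trace.
    """
    config = config or IPFConfig()
    if (vectors.x.size, vectors.y.size, vectors.z.size) != mask.shape:
        raise ValueError(
            f"vector lengths {(vectors.x.size, vectors.y.size, vectors.z.size)} "
            f"do not match mask shape {mask.shape}")
    if not vectors.reconstructable or not (vectors.x.sum() > 0
                                           and vectors.y.sum() > 0
                                           and vectors.z.sum() > 0):
        raise ValueError(
            f"gene {vectors.gene_id!r} not reconstructable: "
            "an axis profile is all zero")

    R = mask.values.astype(float)
    eps = config.epsilon_denominator
    loss_trace: list[float] = []
    last_unassigned: dict[str, list[tuple[int, float]]] = {}
    for it in range(1, config.iterations + 1):
        last_unassigned = {}
        for axis, marginal in zip("xyz", (vectors.x, vectors.y, vectors.z)):
            R, unassigned = ipf_step_axis(R, marginal, axis, eps)
            if unassigned:
                last_unassigned[axis] = unassigned
        if it % config.loss_every == 0 or it == config.iterations:
            loss_trace.append(ipf_loss(R, vectors))

    warnings = [
        {"kind": "unassignable_mass", "axis": axis,
         "section": i + 1, "mass": mass}
        for axis, pairs in last_unassigned.items() for i, mass in pairs
    ]
    if warnings:
        logger.warning("gene %s: %d section(s) with unassignable mass",
                       vectors.gene_id, len(warnings))
    return Reconstruction3D(gene_id=vectors.gene_id, values=R,
                            iterations_run=config.iterations,
                            loss_trace=loss_trace, warnings=warnings)


def reconstruct_batch(dataset: TomoSeqDataset, mask: Mask3D,
                      gene_ids: list[str] | None = None,
                      config: IPFConfig | None = None,
                      normalize: bool = True,
                      ) -> tuple[dict[str, Reconstruction3D], dict]:
    """Preprocess and fit a list of genes; returns (reconstructions, report).

    Normalization statistics (mask marginals, section totals, T) are shared
    across genes, so the batch equals the per-gene path exactly while doing
    the matrix-level work once.  Genes whose profiles vanish on an axis are
    skipped and reported, not fatal.
    """
    if gene_ids is None:
        gene_ids = list(dataset.gene_ids)
    if not gene_ids:
        raise ValueError("gene_ids is empty")
    missing = [g for g in gene_ids if g not in set(dataset.gene_ids)]
    if missing:
        raise KeyError(f"genes not in dataset: {missing}")

    if normalize:
        marginals = compute_mask_marginals(mask)
        normalized = intersection_normalize(dataset, marginals)
    else:
        normalized = dataset

    results: dict[str, Reconstruction3D] = {}
    skipped: dict[str, list[str]] = {}
    for gene in gene_ids:
        vectors = common_scale(dataset, normalized, gene)
        if not vectors.reconstructable:
            skipped[gene] = vectors.notes
            continue
        results[gene] = ipf_fit(vectors, mask, config)
    report = {"n_reconstructed": len(results), "skipped": skipped}
    return results, report
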