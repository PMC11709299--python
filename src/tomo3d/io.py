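"""Containers and on-disk formats for tomo-seq data, masks, and reconstructions.

A tomo-seq experiment sections one sample along three orthogonal axes and
sequences each section, yielding one genes x sections count matrix per
axis.  The three matrices share a gene index; section columns are in
anatomical order.  Masks and reconstructions are 3D volumes stored as NRRD
(single-file, language-portable); masks may alternatively live in a
directory of per-slice CSVs with a JSON sidecar, which is human-editable.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nrrd import read_nrrd, write_nrrd

logger = logging.getLogger(__name__)

DEFAULT_AXIS_LABELS = ("x", "y", "z")


@dataclass
class TomoSeqDataset:
    """Three genes x sections matrices sharing one gene index.

    ``X``, ``Y``, ``Z`` hold the 1D section profiles along the three
    orthogonal sectioning axes; row g of each matrix is the profile of
    ``gene_ids[g]``.  ``normalized`` records which preprocessing stages
    have been applied (e.g. ``("intersection",)``) so stages cannot be
    applied twice.
    """

    gene_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS
    normalized: tuple[str, ...] = ()

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene_ids contains duplicates")
        for label, mat in zip("XYZ", (self.X, self.Y, self.Z)):
            if mat.ndim != 2 or mat.shape[0] != n:
                raise ValueError(
                    f"{label} must be a matrix with {n} rows, got shape {mat.shape}")
            if mat.shape[1] < 1:
                raise ValueError(f"{label} must have at least one section")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{label} contains non-finite values")
            if np.any(mat < 0):
                raise ValueError(f"{label} contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def shape3d(self) -> tuple[int, int, int]:
        """(lx, ly, lz): section counts along the three axes."""
        return (self.X.shape[1], self.Y.shape[1], self.Z.shape[1])

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene ID: {gene_id!r}") from None

    def gene_vectors(self, gene_id: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        g = self.gene_index(gene_id)
        return self.X[g], self.Y[g], self.Z[g]


@dataclass
class Mask3D:
    """Binary lx x ly x lz support volume: 1 where sample material exists."""

    values: np.ndarray
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.values.shape}")
        if not np.all(np.isin(self.values, (0, 1))):
            raise ValueError("mask elements must be exactly 0 or 1")
        self.values = self.values.astype(np.uint8)
        if not self.values.any():
            raise ValueError("mask is all zero: no sample material")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        """Number of 1-voxels (sample material volume in voxel units)."""
        return int(self.values.sum())


@dataclass
class Reconstruction3D:
    """Reconstructed 3D expression volume for one gene, with its loss trace.

    ``loss_trace`` holds the squared-marginal-residual loss recorded after
    IPF iteration sets; ``warnings`` collects structured notes such as mass
    that could not be assigned because a section's mask slice is empty.
    """

    gene_id: str
    values: np.ndarray
    iterations_run: int = 0
    loss_trace: list[float] = field(default_factory=list)
    warnings: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("reconstruction values must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstruction contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("reconstruction contains negative values")


def read_tomoseq_csv(path_x, path_y, path_z,
                     axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS,
                     ) -> tuple[TomoSeqDataset, dict]:
    """Read three per-axis tomo-seq CSVs into one dataset.

    Each CSV has a header row, gene IDs in the first column and sections in
    anatomical order in the remaining columns.  The dataset is restricted
    to the genes present in all three files, in the order of the first
    file; dropped genes are listed in the returned report, not silently
    discarded.
    """
    frames = []
    for path in (path_x, path_y, path_z):
        df = pd.read_csv(path, header=0, dtype={0: str})
        df = df.set_index(df.columns[0])
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene IDs {dupes}")
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = df.index[bad.isna()][0]
                raise ValueError(
                    f"{path}: non-numeric value at gene {row!r}, column {col!r}")
        mat = df.to_numpy(dtype=float)
        if (mat < 0).any():
            i, j = np.argwhere(mat < 0)[0]
            raise ValueError(
                f"{path}: negative value at gene {df.index[i]!r}, "
                f"column {df.columns[j]!r}")
        frames.append(df)

    common = [g for g in frames[0].index
              if g in set(frames[1].index) and g in set(frames[2].index)]
    if not common:
        raise ValueError("no gene IDs shared by all three axis files")
    dropped = {
        str(p): sorted(set(f.index) - set(common))
        for p, f in zip((path_x, path_y, path_z), frames)
    }
    n_dropped = sum(len(v) for v in dropped.values())
    if n_dropped:
        logger.warning("dropped %d gene rows absent from at least one axis",
                       n_dropped)
    dataset = TomoSeqDataset(
        gene_ids=list(common),
        X=frames[0].loc[common].to_numpy(dtype=float),
        Y=frames[1].loc[common].to_numpy(dtype=float),
        Z=frames[2].loc[common].to_numpy(dtype=float),
        axis_labels=axis_labels,
    )
    report = {"n_genes": len(common), "dropped": dropped}
    return dataset, report


def write_tomoseq_csv(dataset: TomoSeqDataset, path_x, path_y, path_z) -> None:
    """Write one CSV per axis; inverse of :func:`read_tomoseq_csv`."""
    for path, mat in zip((path_x, path_y, path_z),
                         (dataset.X, dataset.Y, dataset.Z)):
        df = pd.DataFrame(mat, index=pd.Index(dataset.gene_ids, name="gene_id"),
                          columns=[f"section_{i + 1}" for i in range(mat.shape[1])])
        df.to_csv(path)


_SLICE_RE = re.compile(r"slice_(\d+)\.csv$")


def read_mask(path) -> Mask3D:
    """Read a mask from an NRRD file or a slice-CSV directory.

    A slice directory holds ``slice_0000.csv`` .. ``slice_{lz-1}.csv`` (each
    an lx x ly matrix, no header) plus ``meta.json`` with lx, ly, lz and
    axis_labels.  Nonzero non-1 values are coerced to 1 with a warning.
    """
    path = Path(path)
    if path.is_dir():
        meta = json.loads((path / "meta.json").read_text())
        lx, ly, lz = meta["lx"], meta["ly"], meta["lz"]
        slices = []
        for k in range(lz):
            fp = path / f"slice_{k:04d}.csv"
            arr = np.loadtxt(fp, delimiter=",", ndmin=2)
            if arr.shape != (lx, ly):
                raise ValueError(
                    f"{fp}: slice shape {arr.shape} != ({lx}, {ly})")
            slices.append(arr)
        values = np.stack(slices, axis=-1)
        labels = tuple(meta.get("axis_labels", DEFAULT_AXIS_LABELS))
        voxel_size = tuple(meta["voxel_size"]) if meta.get("voxel_size") else None
    else:
        values, fields = read_nrrd(path)
        labels = tuple(fields.get("axis labels", "x y z").replace('"', "").split())
        if len(labels) != 3:
            labels = DEFAULT_AXIS_LABELS
        voxel_size = None

    n_coerced = int(np.sum((values != 0) & (values != 1)))
    if n_coerced:
        logger.warning("read_mask: coerced %d nonzero values to 1", n_coerced)
    return Mask3D(values=(values != 0).astype(np.uint8), axis_labels=labels,
                  voxel_size=voxel_size)


def write_mask(mask: Mask3D, path) -> None:
    """Write a mask as NRRD (uint8)."""
    extra = {"axis labels": " ".join(f'"{l}"' for l in mask.axis_labels)}
    write_nrrd(path, mask.values.astype(np.uint8), extra_fields=extra)


def write_mask_slices(mask: Mask3D, directory) -> None:
    """Write a mask as a slice-CSV directory with a meta.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lx, ly, lz = mask.shape
    meta = {"lx": lx, "ly": ly, "lz": lz,
            "axis_labels": list(mask.axis_labels),
            "voxel_size": list(mask.voxel_size) if mask.voxel_size else None}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    for k in range(lz):
        np.savetxt(directory / f"slice_{k:04d}.csv", mask.values[:, :, k],
                   fmt="%d", delimiter=",")


def write_reconstruction(recon: Reconstruction3D, path) -> None:
    """Write a reconstruction as NRRD plus a JSON metadata sidecar."""
    path = Path(path)
    write_nrrd(path, recon.values.astype(np.float64))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "gene_id": recon.gene_id,
        "iterations_run": recon.iterations_run,
        "loss_trace": list(map(float, recon.loss_trace)),
        "warnings": recon.warnings,
    }, indent=1))


def read_reconstruction(path) -> Reconstruction3D:
    path = Path(path)
    values, _ = read_nrrd(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return Reconstruction3D(
        gene_id=meta.get("gene_id", path.stem),
        values=values,
        iterations_run=meta.get("iterations_run", 0),
        loss_trace=meta.get("loss_trace", []),
        warnings=meta.get("warnings", []),
    )
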