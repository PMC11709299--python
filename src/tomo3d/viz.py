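"""Static rendering of reconstructions: section heatmaps, sweeps, 3D points.

Cross-sections are drawn as heatmaps with voxels outside the mask shown as
background.  When sweeping all sections of an axis, one color scale (0 to
the maximum over the whole masked volume) is shared across frames so
sections are comparable.  The 3D export writes an ASCII PLY point cloud:
mask voxels above a value threshold colored by expression, the remaining
mask voxels as faint shape points.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import imageio.v3 as iio
import matplotlib.pyplot as plt
import numpy as np

from .io import Mask3D, Reconstruction3D

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class RenderSpec:
    axis: str = "z"
    section_index: int | str = "all"
    colormap: str = "viridis"
    value_range: tuple[float, float] | None = None
    show_mask_outline: bool = True
    point_threshold: float = 0.2  # fraction of max, 3D export only

    def __post_init__(self):
        if self.axis not in _AXIS_INDEX:
            raise ValueError(f"axis must be x, y or z, got {self.axis!r}")
        if not 0.0 <= self.point_threshold <= 1.0:
            raise ValueError("point_threshold must be in [0, 1]")


def _take_section(values: np.ndarray, axis: str, index: int) -> np.ndarray:
    ax = _AXIS_INDEX[axis]
    if not 0 <= index < values.shape[ax]:
        raise ValueError(
            f"section {index} out of range for axis {axis} "
            f"(extent {values.shape[ax]})")
    return np.take(values, index, axis=ax)


def _render_frame(recon_values, mask_values, axis, index, spec, vmin, vmax):
    section = _take_section(recon_values, axis, index)
    mask_section = _take_section(mask_values, axis, index).astype(bool)
    shown = np.where(mask_section, section, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
    cmap = plt.get_cmap(spec.colormap).copy()
    cmap.set_bad("white")
    im = ax.imshow(shown.T, origin="lower", cmap=cmap, vmin=vmin, vmax=vmax)
    if spec.show_mask_outline:
        ax.contour(mask_section.T.astype(float), levels=[0.5],
                   colors="grey", linewidths=0.8)
    ax.set_title(f"{axis}-section {index + 1}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.canvas.draw()
    frame = np.asarray(fig.canvas.buffer_rgba())[:, :, :3].copy()
    plt.close(fig)
    return frame


def render_section(recon: Reconstruction3D, mask: Mask3D, spec: RenderSpec,
                   out_path) -> list[Path]:
    """Write a PNG per requested section (or a GIF sweep for "all" with a
    .gif output path).  Returns the paths written."""
    if recon.values.shape != mask.shape:
        raise ValueError("reconstruction and mask shapes differ")
    masked = recon.values[mask.values.astype(bool)]
    vmin, vmax = spec.value_range or (0.0, float(masked.max()) or 1.0)
    out_path = Path(out_path)
    axis = spec.axis
    extent = recon.values.shape[_AXIS_INDEX[axis]]

    if spec.section_index == "all":
        frames = [_render_frame(recon.values, mask.values, axis, i, spec,
                                vmin, vmax)
                  for i in range(extent)]
        if out_path.suffix.lower() == ".gif":
            # frames can differ by a few pixels; pad to a common canvas
            h = max(f.shape[0] for f in frames)
            w = max(f.shape[1] for f in frames)
            padded = []
            for f in frames:
                canvas = np.full((h, w, 3), 255, dtype=np.uint8)
                canvas[:f.shape[0], :f.shape[1]] = f
                padded.append(canvas)
            iio.imwrite(out_path, padded, duration=200, loop=0)
            return [out_path]
        paths = []
        for i, frame in enumerate(frames):
            p = out_path.with_name(f"{out_path.stem}_{axis}{i + 1:04d}.png")
            iio.imwrite(p, frame)
            paths.append(p)
        return paths

    frame = _render_frame(recon.values, mask.values, axis,
                          int(spec.section_index), spec, vmin, vmax)
    iio.imwrite(out_path, frame)
    return [out_path]


def _value_colors(values: np.ndarray, colormap: str) -> np.ndarray:
    vmax = values.max() or 1.0
    rgba = plt.get_cmap(colormap)(values / vmax)
    return (rgba[:, :3] * 255).astype(np.uint8)


def export_points(recon: Reconstruction3D, mask: Mask3D, spec: RenderSpec,
                  ply_path, png_path=None) -> dict:
    """Write an ASCII PLY point cloud and a static projection PNG.

    Mask voxels with value >= point_threshold * max are colored by value;
    the remaining mask voxels are faint grey shape points.  Point
    coordinates are voxel centers (i + 0.5, j + 0.5, k + 0.5).
    """
    if recon.values.shape != mask.shape:
        raise ValueError("reconstruction and mask shapes differ")
    support = mask.values.astype(bool)
    coords = np.argwhere(support) + 0.5
    values = recon.values[support]
    vmax = float(values.max())
    hot = values >= spec.point_threshold * vmax if vmax > 0 else \
        np.zeros(values.shape, dtype=bool)
    if not hot.any():
        import logging
        logging.getLogger(__name__).warning(
            "export_points: no voxel above threshold; writing mask-only cloud")

    colors = np.full((len(values), 3), 230, dtype=np.uint8)  # faint shape
    colors[hot] = _value_colors(values[hot], spec.colormap)

    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(coords)}",
        "property float x", "property float y", "property float z",
        "property uchar red", "property uchar green", "property uchar blue",
        "end_header",
    ]
    body = "\n".join(
        f"{c[0]:g} {c[1]:g} {c[2]:g} {r} {g} {b}"
        for c, (r, g, b) in zip(coords, colors))
    Path(ply_path).write_text("\n".join(lines) + "\n" + body + "\n")

    if png_path is not None:
        fig, ax = plt.subplots(figsize=(4, 4), dpi=100)
        ax.scatter(coords[~hot, 0], coords[~hot, 1], s=1, c="#dddddd")
        if hot.any():
            sc = ax.scatter(coords[hot, 0], coords[hot, 1], s=3,
                            c=values[hot], cmap=spec.colormap)
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_xlabel(mask.axis_labels[0])
        ax.set_ylabel(mask.axis_labels[1])
        ax.set_aspect("equal")
        fig.savefig(png_path)
        plt.close(fig)

    return {"n_points": int(len(coords)), "n_colored": int(hot.sum())}
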