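"""Programmatic builders for 3D binary masks.

The mask marks the voxels occupied by sample material; it is both the
initial value and the support constraint of the reconstruction.  Builders
use a voxel-center inclusion test: voxel (i, j, k) has its center at
continuous coordinates (i + 0.5, j + 0.5, k + 0.5) and is inside a shape
iff its center is.  This is unambiguous and resolution-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DEFAULT_AXIS_LABELS, Mask3D


@dataclass
class ShapeSpec:
    """Geometric description of a mask shape, all in voxel units."""

    kind: str  # ellipsoid | hemisphere_shell | extruded_outline
    shape: tuple[int, int, int]
    center: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] | None = None
    shell_thickness: float | None = None
    cut_axis: int = 1          # hemisphere: axis of the equatorial cut plane
    keep_side: str = "low"     # hemisphere: which half-space to keep
    outline: np.ndarray | None = None
    extrusion_axis: int = 2
    axis_labels: tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self):
        if any(s < 1 for s in self.shape):
            raise ValueError("shape components must be >= 1")
        if self.center is None:
            self.center = tuple(s / 2 for s in self.shape)
        if self.radii is not None and any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")


def _center_grids(shape):
    """Voxel-center coordinate grids for a given array shape."""
    axes = [np.arange(s) + 0.5 for s in shape]
    return np.meshgrid(*axes, indexing="ij")


def _inside_ellipsoid(grids, center, radii):
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def make_ellipsoid_mask(spec: ShapeSpec) -> Mask3D:
    """Solid ellipsoid mask: voxel centers inside the ellipsoid are 1."""
    if spec.kind != "ellipsoid":
        raise ValueError(f"expected kind 'ellipsoid', got {spec.kind!r}")
    if spec.radii is None:
        raise ValueError("ellipsoid requires radii")
    grids = _center_grids(spec.shape)
    inside = _inside_ellipsoid(grids, spec.center, spec.radii)
    if not inside.any():
        raise ValueError("ellipsoid mask is empty: no voxel center inside")
    return Mask3D(inside.astype(np.uint8), axis_labels=spec.axis_labels)


def make_hemisphere_shell_mask(spec: ShapeSpec) -> Mask3D:
    """Hollow hemisphere: ellipsoidal shell cut at the equatorial plane.

    A voxel is 1 iff it is inside the outer ellipsoid, outside the inner
    ellipsoid (radii shrunk by ``shell_thickness``), and on the retained
    side of the plane through the center normal to ``cut_axis``.
    """
    if spec.kind != "hemisphere_shell":
        raise ValueError(f"expected kind 'hemisphere_shell', got {spec.kind!r}")
    if spec.radii is None or spec.shell_thickness is None:
        raise ValueError("hemisphere_shell requires radii and shell_thickness")
    if spec.shell_thickness >= min(spec.radii):
        raise ValueError("shell_thickness must be < min(radii)")
    grids = _center_grids(spec.shape)
    outer = _inside_ellipsoid(grids, spec.center, spec.radii)
    inner_radii = tuple(r - spec.shell_thickness for r in spec.radii)
    inner = _inside_ellipsoid(grids, spec.center, inner_radii)
    coord = grids[spec.cut_axis]
    c = spec.center[spec.cut_axis]
    side = coord <= c if spec.keep_side == "low" else coord >= c
    values = outer & ~inner & side
    if not values.any():
        raise ValueError("hemisphere shell mask is empty")
    return Mask3D(values.astype(np.uint8), axis_labels=spec.axis_labels)


def extrude_outline_mask(spec: ShapeSpec,
                         per_slice_outlines: list[np.ndarray] | None = None,
                         ) -> Mask3D:
    """Stack 2D binary outlines along an axis into a 3D mask.

    With a single ``spec.outline``, that outline is repeated along the
    extrusion axis; with ``per_slice_outlines``, slice k of the mask is
    outline k (the list length must equal the axis extent).  This is the
    programmatic counterpart of drawing one section outline at a time.
    """
    if spec.kind != "extruded_outline":
        raise ValueError(f"expected kind 'extruded_outline', got {spec.kind!r}")
    axis = spec.extrusion_axis
    extent = spec.shape[axis]
    plane_shape = tuple(s for d, s in enumerate(spec.shape) if d != axis)
    if per_slice_outlines is None:
        if spec.outline is None:
            raise ValueError("need spec.outline or per_slice_outlines")
        outlines = [np.asarray(spec.outline)] * extent
    else:
        if len(per_slice_outlines) != extent:
            raise ValueError(
                f"got {len(per_slice_outlines)} outlines for axis extent {extent}")
        outlines = [np.asarray(o) for o in per_slice_outlines]
    for o in outlines:
        if o.shape != plane_shape:
            raise ValueError(f"outline shape {o.shape} != plane {plane_shape}")
        if not np.all(np.isin(o, (0, 1))):
            raise ValueError("outlines must be binary")
    values = np.stack(outlines, axis=axis)
    return Mask3D(values.astype(np.uint8), axis_labels=spec.axis_labels)


def build_mask(spec: ShapeSpec, **kwargs) -> Mask3D:
    """Dispatch to the builder matching ``spec.kind``."""
    builders = {
        "ellipsoid": make_ellipsoid_mask,
        "hemisphere_shell": make_hemisphere_shell_mask,
        "extruded_outline": extrude_outline_mask,
    }
    try:
        builder = builders[spec.kind]
    except KeyError:
        raise ValueError(f"unknown shape kind: {spec.kind!r}") from None
    return builder(spec, **kwargs)
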