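"""Minimal NRRD volume reader/writer.

Supports the subset of the NRRD format this package emits: 3D arrays,
``raw`` (little-endian) or ``ascii`` encoding, detached headers not
supported.  The first axis in ``sizes`` is the fastest-varying axis of
the data stream, per the NRRD convention, so arrays are serialized in
Fortran order.
"""

from __future__ import annotations

import numpy as np

_MAGIC = "NRRD000"

_TYPE_TO_DTYPE = {
    "signed char": "i1", "int8": "i1", "int8_t": "i1",
    "uchar": "u1", "unsigned char": "u1", "uint8": "u1", "uint8_t": "u1",
    "short": "i2", "int16": "i2", "int16_t": "i2",
    "ushort": "u2", "uint16": "u2", "uint16_t": "u2",
    "int": "i4", "int32": "i4", "int32_t": "i4",
    "uint": "u4", "uint32": "u4", "uint32_t": "u4",
    "longlong": "i8", "int64": "i8", "int64_t": "i8",
    "ulonglong": "u8", "uint64": "u8", "uint64_t": "u8",
    "float": "f4", "double": "f8",
}
_DTYPE_TO_TYPE = {
    np.dtype(np.uint8): "uint8",
    np.dtype(np.int32): "int32",
    np.dtype(np.int64): "int64",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
}


def write_nrrd(path, values: np.ndarray, *, encoding: str = "raw",
               extra_fields: dict | None = None) -> None:
    """Write a 3D array as an attached-header NRRD file."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {values.shape}")
    if values.dtype not in _DTYPE_TO_TYPE:
        values = values.astype(np.float64)
    if encoding not in ("raw", "ascii", "text", "txt"):
        raise ValueError(f"unsupported NRRD encoding: {encoding!r}")
    lines = [
        "NRRD0004",
        "# written by tomo3d",
        f"type: {_DTYPE_TO_TYPE[values.dtype]}",
        "dimension: 3",
        f"sizes: {values.shape[0]} {values.shape[1]} {values.shape[2]}",
        f"encoding: {encoding}",
    ]
    if encoding == "raw":
        lines.append("endian: little")
    for key, val in (extra_fields or {}).items():
        lines.append(f"{key}: {val}")
    header = "\n".join(lines) + "\n\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        flat = values.ravel(order="F")
        if encoding == "raw":
            fh.write(flat.astype(flat.dtype.newbyteorder("<")).tobytes())
        else:
            fh.write(" ".join(repr(v) for v in flat.tolist()).encode("ascii"))


def read_nrrd(path) -> tuple[np.ndarray, dict]:
    """Read an attached-header NRRD file; returns (array, header fields)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    sep = blob.find(b"\n\n")
    if not blob.startswith(_MAGIC.encode()) or sep < 0:
        raise ValueError(f"{path}: not a valid NRRD file")
    fields: dict[str, str] = {}
    for line in blob[:sep].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.strip().lstrip("=").strip()
    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(f"{path}: only 3D NRRD volumes are supported")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    typ = fields["type"]
    if typ not in _TYPE_TO_DTYPE:
        raise ValueError(f"{path}: unsupported NRRD type {typ!r}")
    encoding = fields.get("encoding", "raw")
    data = blob[sep + 2:]
    if encoding == "raw":
        endian = "<" if fields.get("endian", "little") == "little" else ">"
        flat = np.frombuffer(data, dtype=endian + _TYPE_TO_DTYPE[typ],
                             count=int(np.prod(sizes)))
    elif encoding in ("ascii", "text", "txt"):
        flat = np.array(data.decode("ascii").split(), dtype=float)
        flat = flat.astype(_TYPE_TO_DTYPE[typ])
    else:
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    return flat.reshape(sizes, order="F").copy(), fields
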