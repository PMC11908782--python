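"""Minimal reader/writer for ImageJ ``.roi`` files and ``RoiSet.zip`` archives.

Implements the subset of the ImageJ ROI binary format needed for
manually drawn cell-body outlines: rectangle, oval, polygon and
freehand ROIs.  All fields are big-endian.  Layout of the 64-byte
header (offsets in bytes):

    0-3   magic "Iout"
    4-5   version
    6     roi type (0 polygon, 1 rect, 2 oval, 7 freehand)
    8-15  top, left, bottom, right (int16 each)
    16-17 n coordinates (polygon/freehand)
    64-   x coords relative to left (int16 * n), then y relative to top

Only the geometry is preserved; styling fields are written as zeros,
which ImageJ accepts.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass

import numpy as np

__all__ = ["RoiGeometry", "read_roi_bytes", "write_roi_bytes", "read_roi_zip", "write_roi_zip"]

_MAGIC = b"Iout"
_HEADER_SIZE = 64

POLYGON, RECT, OVAL, FREEHAND = 0, 1, 2, 7
_SUPPORTED = {POLYGON, RECT, OVAL, FREEHAND}


class RoiFormatError(ValueError):
    """Raised for files that are not parseable ImageJ ROIs."""


@dataclass(frozen=True)
class RoiGeometry:
    """Geometry of one ROI: type, bounding box, optional vertex list."""

    name: str
    roi_type: int
    top: int
    left: int
    bottom: int
    right: int
    xs: np.ndarray | None = None  # absolute image coords for polygons
    ys: np.ndarray | None = None

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def height(self) -> int:
        return self.bottom - self.top


def read_roi_bytes(data: bytes, name: str = "roi") -> RoiGeometry:
    if len(data) < _HEADER_SIZE or data[:4] != _MAGIC:
        raise RoiFormatError(f"{name}: not an ImageJ ROI file")
    roi_type = data[6]
    if roi_type not in _SUPPORTED:
        raise RoiFormatError(f"{name}: unsupported ROI type {roi_type}")
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    (n,) = struct.unpack(">h", data[16:18])
    xs = ys = None
    if roi_type in (POLYGON, FREEHAND):
        need = _HEADER_SIZE + 4 * n
        if len(data) < need:
            raise RoiFormatError(f"{name}: truncated coordinate block")
        rel = np.frombuffer(data[_HEADER_SIZE:need], dtype=">i2").astype(int)
        xs = rel[:n] + left
        ys = rel[n:] + top
    return RoiGeometry(name, roi_type, top, left, bottom, right, xs, ys)


def write_roi_bytes(roi: RoiGeometry) -> bytes:
    if roi.roi_type not in _SUPPORTED:
        raise RoiFormatError(f"unsupported ROI type {roi.roi_type}")
    n = 0 if roi.xs is None else len(roi.xs)
    header = bytearray(_HEADER_SIZE)
    header[:4] = _MAGIC
    struct.pack_into(">h", header, 4, 228)  # version written by modern ImageJ
    header[6] = roi.roi_type
    struct.pack_into(">4h", header, 8, roi.top, roi.left, roi.bottom, roi.right)
    struct.pack_into(">h", header, 16, n)
    body = b""
    if n:
        rel_x = (np.asarray(roi.xs, dtype=int) - roi.left).astype(">i2")
        rel_y = (np.asarray(roi.ys, dtype=int) - roi.top).astype(">i2")
        body = rel_x.tobytes() + rel_y.tobytes()
    return bytes(header) + body


def read_roi_zip(path) -> list[RoiGeometry]:
    try:
        with zipfile.ZipFile(path) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith(".roi")]
            rois = [
                read_roi_bytes(zf.read(n), name=n.rsplit("/", 1)[-1][:-4]) for n in sorted(names)
            ]
    except (zipfile.BadZipFile, OSError) as exc:
        raise RoiFormatError(f"cannot read ROI archive {path}: {exc}") from exc
    if not rois:
        raise RoiFormatError(f"ROI archive {path} contains no .roi entries")
    return rois


def write_roi_zip(rois: list[RoiGeometry], path) -> None:
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for roi in rois:
            zf.writestr(f"{roi.name}.roi", write_roi_bytes(roi))
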