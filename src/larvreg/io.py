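"""Readers and writers for the formats the pipeline touches.

Images travel as multi-page TIFF (one page per z-slice) or uncompressed
MetaImage (``.mha``); landmark sets as CSV tables ``label,x_um,y_um,z_um``
with one header line.  A separate importer accepts the tab-separated
point lists exported by Fiji's landmarks plugin.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile

from .model import LandmarkSet, VolumetricImage

__all__ = [
    "read_stack",
    "write_stack",
    "read_landmarks",
    "write_landmarks",
    "read_fiji_points",
]

_MET_TYPES = {
    "MET_UCHAR": np.uint8,
    "MET_CHAR": np.int8,
    "MET_USHORT": np.uint16,
    "MET_SHORT": np.int16,
    "MET_UINT": np.uint32,
    "MET_INT": np.int32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}

_TIFF_DTYPES = (np.uint8, np.uint16, np.float32)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def read_stack(
    path,
    spacing: Optional[Tuple[float, float, float]] = None,
    channel_label: str = "other",
) -> VolumetricImage:
    """Read a 3D volume from a multi-page TIFF or a MetaImage file.

    ``spacing`` overrides/replaces file metadata; if the file carries no
    spacing and none is supplied, an error is raised (spacing is never
    silently defaulted — all downstream geometry is in μm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".mha", ".mhd"):
        data, file_spacing, origin = _read_metaimage(path)
        if data.ndim == 4:
            raise ValueError(f"{path}: vector-valued volume is not a scalar image")
    else:
        data, file_spacing, origin = _read_tiff(path)
    if data.ndim == 2:
        raise ValueError(f"{path}: 2D-only input; a z-stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 axes, got {data.ndim}")
    use_spacing = spacing if spacing is not None else file_spacing
    if use_spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in file metadata; pass spacing=(sx, sy, sz)"
        )
    return VolumetricImage(
        data=data, spacing=tuple(use_spacing), origin=origin, channel_label=channel_label
    )


def write_stack(img: VolumetricImage, path) -> None:
    """Write a volume so that :func:`read_stack` returns identical data/spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".mha", ".mhd"):
        _write_metaimage(img.data, img.spacing, img.origin, path)
        return
    if not any(img.data.dtype == np.dtype(d) for d in _TIFF_DTYPES):
        raise ValueError(
            f"TIFF output supports dtypes {[np.dtype(d).name for d in _TIFF_DTYPES]}; "
            f"got {img.data.dtype} — use .mha for other pixel types"
        )
    sx, sy, sz = img.spacing
    # pages are z-slices; page rows are y, columns are x
    pages = np.ascontiguousarray(img.data.transpose(2, 1, 0))
    tifffile.imwrite(
        path,
        pages,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={
            "spacing": sz,
            "unit": "um",
            "axes": "ZYX",
            "larvreg_origin": json.dumps(list(img.origin)),
        },
    )


def _read_tiff(path: Path):
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = None
        origin = (0.0, 0.0, 0.0)
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        try:
            xres = page.tags["XResolution"].value
            yres = page.tags["YResolution"].value
            sx = xres[1] / xres[0]
            sy = yres[1] / yres[0]
        except (KeyError, ZeroDivisionError):
            sx = sy = None
        sz = meta.get("spacing")
        if sx is not None and sz is not None:
            spacing = (float(sx), float(sy), float(sz))
        if "larvreg_origin" in meta:
            origin = tuple(json.loads(meta["larvreg_origin"]))
    if data.ndim == 2:
        return data, spacing, origin
    if data.ndim != 3:
        raise ValueError(f"{path}: non-scalar or >3D TIFF (shape {data.shape})")
    return np.ascontiguousarray(data.transpose(2, 1, 0)), spacing, origin


# ---------------------------------------------------------------------------
# MetaImage (.mha, uncompressed, LOCAL data)
# ---------------------------------------------------------------------------

def _write_metaimage(data: np.ndarray, spacing, origin, path: Path) -> None:
    n_channels = 1
    arr = np.asarray(data)
    if arr.ndim == 4:
        n_channels = arr.shape[-1]
        raw = np.ascontiguousarray(arr.transpose(2, 1, 0, 3))
    elif arr.ndim == 3:
        raw = np.ascontiguousarray(arr.transpose(2, 1, 0))
    else:
        raise ValueError(f"MetaImage output requires 3 or 4 axes, got {arr.ndim}")
    try:
        met_type = _MET_NAMES[arr.dtype]
    except KeyError:
        raise ValueError(f"unsupported dtype for MetaImage: {arr.dtype}") from None
    nx, ny, nz = (arr.shape[0], arr.shape[1], arr.shape[2])
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        "TransformMatrix = 1 0 0 0 1 0 0 0 1\n"
        f"Offset = {origin[0]} {origin[1]} {origin[2]}\n"
        f"ElementSpacing = {spacing[0]} {spacing[1]} {spacing[2]}\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementNumberOfChannels = {n_channels}\n"
        f"ElementType = {met_type}\n"
        "ElementDataFile = LOCAL\n"
    )
    little = raw if raw.dtype.byteorder in ("<", "|", "=") else raw.byteswap()
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(little.tobytes())


def _read_metaimage(path: Path):
    with open(path, "rb") as fh:
        blob = fh.read()
    fields = {}
    pos = 0
    while True:
        eol = blob.index(b"\n", pos)
        line = blob[pos:eol].decode("ascii")
        pos = eol + 1
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
        if key.strip() == "ElementDataFile":
            break
    if fields.get("CompressedData", "False") == "True":
        raise ValueError(f"{path}: compressed MetaImage is not supported")
    dims = tuple(int(v) for v in fields["DimSize"].split())
    spacing = tuple(float(v) for v in fields.get("ElementSpacing", "1 1 1").split())
    origin = tuple(float(v) for v in fields.get("Offset", "0 0 0").split())
    n_channels = int(fields.get("ElementNumberOfChannels", "1"))
    dtype = _MET_TYPES[fields["ElementType"]]
    count = int(np.prod(dims)) * n_channels
    expected = count * np.dtype(dtype).itemsize
    raw = blob[pos:]
    if len(raw) < expected:
        raise ValueError(
            f"{path}: truncated data section ({len(raw)} of {expected} bytes)"
        )
    flat = np.frombuffer(raw[:expected], dtype=dtype)
    if fields.get("BinaryDataByteOrderMSB", "False") == "True":
        flat = flat.byteswap()
    nx, ny, nz = dims
    if n_channels > 1:
        data = flat.reshape(nz, ny, nx, n_channels).transpose(2, 1, 0, 3)
    else:
        data = flat.reshape(nz, ny, nx).transpose(2, 1, 0)
    return np.ascontiguousarray(data), spacing, origin


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

_LANDMARK_HEADER = ["label", "x_um", "y_um", "z_um"]


def read_landmarks(path, frame_id: str = "") -> LandmarkSet:
    """Read a ``label,x_um,y_um,z_um`` CSV; an empty file yields an empty set."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, coords = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        return LandmarkSet([], np.zeros((0, 3)), frame_id=frame_id)
    start = 1 if [c.strip().lower() for c in rows[0][:4]] == _LANDMARK_HEADER else 0
    for row in rows[start:]:
        if len(row) < 4:
            raise ValueError(f"{path}: malformed landmark row {row!r}")
        labels.append(row[0].strip())
        try:
            coords.append([float(row[1]), float(row[2]), float(row[3])])
        except ValueError:
            raise ValueError(f"{path}: non-numeric coordinates in row {row!r}") from None
    return LandmarkSet(labels, np.asarray(coords), frame_id=frame_id)


def write_landmarks(lms: LandmarkSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LANDMARK_HEADER)
        for label, (x, y, z) in lms:
            writer.writerow([label, repr(float(x)), repr(float(y)), repr(float(z))])


def read_fiji_points(path, frame_id: str = "") -> LandmarkSet:
    """Import a Fiji landmarks-plugin point list (tab/whitespace separated).

    Each line is ``<name> <x> <y> <z>``; the name may contain spaces, the
    last three whitespace-separated fields must be numeric.
    """
    path = Path(path)
    labels, coords = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed point line {line!r}")
            try:
                xyz = [float(v) for v in parts[-3:]]
            except ValueError:
                raise ValueError(f"{path}: non-numeric coordinates in {line!r}") from None
            labels.append(" ".join(parts[:-3]))
            coords.append(xyz)
    return LandmarkSet(labels, np.asarray(coords).reshape(len(labels), 3), frame_id=frame_id)
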