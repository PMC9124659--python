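"""Readers and writers for tilt series, volumes, angle and shift files.

MRC support is a small self-contained MRC2014 implementation (mode 2 float
output; modes 0/1/2/6 and both byte orders on input) so the package has no
binary-format dependencies; TIFF stacks go through :mod:`tifffile`.
"""

from __future__ import annotations

import logging
import os
import struct
from pathlib import Path

import numpy as np
import tifffile

from .geometry import TiltSeries, Volume
from .warp import ShiftSet

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_tilt_series",
    "write_tilt_series",
    "read_volume",
    "write_volume",
    "read_angles",
    "write_angles",
    "read_shifts",
    "write_shifts",
]

log = logging.getLogger(__name__)

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_HEADER_SIZE = 1024


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    """Write a 3D array as little-endian MRC2014 mode 2 (32-bit float)."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"MRC writer expects 2D/3D data, got shape {data.shape}")
    nz, ny, nx = data.shape
    f32 = np.ascontiguousarray(data, dtype="<f4")
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, 2)  # MODE 2
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into(
        "<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size
    )  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(f32.min()), float(f32.max()), float(f32.mean())
    )
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(f32.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(f32.tobytes())


def read_mrc(path) -> np.ndarray:
    """Read an MRC file into a float64 array of shape (nz, ny, nx)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise OSError(f"{path}: truncated MRC header")
        order = "<"
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        stamp = header[212:216]
        if stamp[0] == 0x11:  # big-endian machine stamp
            order = ">"
        elif stamp[0] != 0x44 and mode not in _MRC_MODES:
            order = ">"  # old file without a stamp: fall back to sanity check
        if order == ">":
            nx, ny, nz, mode = struct.unpack_from(">4i", header, 0)
        if mode not in _MRC_MODES:
            raise OSError(f"{path}: unsupported or corrupt MRC mode {mode}")
        if min(nx, ny, nz) < 1:
            raise OSError(f"{path}: invalid MRC dimensions {(nx, ny, nz)}")
        (nsymbt,) = struct.unpack_from(order + "i", header, 92)
        if nsymbt:
            fh.seek(nsymbt, os.SEEK_CUR)
        dtype = np.dtype(_MRC_MODES[mode]).newbyteorder(order)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
    if data.size != count:
        raise OSError(f"{path}: truncated MRC data section")
    return data.reshape(nz, ny, nx).astype(np.float64)


def _is_tiff(path) -> bool:
    return Path(path).suffix.lower() in (".tif", ".tiff")


def read_angles(path) -> np.ndarray:
    """Read a .tlt/.rawtlt file: one tilt angle in degrees per line."""
    angles = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                angles.append(float(line))
    if not angles:
        raise OSError(f"{path}: no angles found")
    return np.asarray(angles)


def write_angles(path, angles_deg) -> None:
    with open(path, "w") as fh:
        for a in np.atleast_1d(angles_deg):
            fh.write(f"{float(a):.4f}\n")


def read_tilt_series(path, angles_path) -> TiltSeries:
    """Load a tilt series from an MRC stack or multi-page TIFF plus a .tlt.

    The angle count must match the stack depth; unsorted angles trigger a
    warning but are kept in file order.
    """
    stack = tifffile.imread(path) if _is_tiff(path) else read_mrc(path)
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    angles = read_angles(angles_path)
    if stack.shape[0] != angles.size:
        raise OSError(
            f"{path}: {stack.shape[0]} images but {angles.size} angles in {angles_path}"
        )
    if np.any(np.diff(angles) <= 0):
        log.warning("%s: tilt angles are not strictly increasing; kept as read",
                    angles_path)
    return TiltSeries(stack, angles)


def write_tilt_series(path, b: TiltSeries, angles_path=None) -> None:
    """Write a tilt series stack (MRC or TIFF by extension) and its angles."""
    if _is_tiff(path):
        tifffile.imwrite(path, b.images.astype(np.float32))
    else:
        write_mrc(path, b.images)
    if angles_path is not None:
        write_angles(angles_path, b.angles_deg)


def read_volume(path) -> Volume:
    if _is_tiff(path):
        return Volume(np.asarray(tifffile.imread(path), dtype=np.float64))
    return Volume(read_mrc(path))


def write_volume(u: Volume, path) -> None:
    if _is_tiff(path):
        tifffile.imwrite(path, u.data.astype(np.float32))
    else:
        write_mrc(path, u.data)


def write_shifts(path, f: ShiftSet, angles_deg) -> None:
    """Write per-angle shifts as TSV with columns angle, f0, f1."""
    angles = np.atleast_1d(angles_deg)
    if angles.size != f.n_angles:
        raise ValueError("angle count does not match shift set")
    with open(path, "w") as fh:
        fh.write("angle_deg\tf0_px\tf1_px\n")
        for a, f0, f1 in zip(angles, f.shifts[0], f.shifts[1]):
            fh.write(f"{float(a):.4f}\t{f0:.6f}\t{f1:.6f}\n")


def read_shifts(path):
    """Read a shifts TSV; returns ``(ShiftSet, angles_deg)``."""
    raw = np.loadtxt(path, skiprows=1)
    raw = np.atleast_2d(raw)
    if raw.shape[1] != 3:
        raise OSError(f"{path}: expected 3 columns (angle, f0, f1)")
    return ShiftSet(raw[:, 1:3].T), raw[:, 0]
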