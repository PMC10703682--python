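"""Minimal MRC2014 reader/writer (mode 2, 32-bit float).

Covers exactly what this package produces and consumes: single images,
image stacks and volumes with a correct pixel size in the header.  Stacks
and volumes are distinguished by the space-group field (``ispg = 0`` for
images/stacks, ``1`` for volumes), per the MRC2014 convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_mrc", "write_mrc"]

_HEADER_BYTES = 1024


def write_mrc(path, data: np.ndarray, pixel_size: float = 1.0, volume: bool | None = None) -> None:
    """Write a 2D image, image stack or volume as MRC2014 mode 2.

    ``volume=None`` treats 3D data as a volume; pass ``volume=False`` for an
    image stack (sections along the first axis).
    """
    data = np.asarray(data, dtype="<f4")
    if data.ndim == 2:
        data = data[None]
        is_volume = False
    elif data.ndim == 3:
        is_volume = True if volume is None else bool(volume)
    else:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    header = np.zeros(_HEADER_BYTES, dtype=np.uint8)
    i4 = header.view("<i4")
    f4 = header.view("<f4")
    i4[0:3] = (nx, ny, nz)
    i4[3] = 2  # mode 2: float32
    i4[7:10] = (nx, ny, nz)  # mx, my, mz
    f4[10:13] = (nx * pixel_size, ny * pixel_size, nz * pixel_size)  # cell a
    f4[13:16] = 90.0  # cell angles
    i4[16:19] = (1, 2, 3)  # axis order
    f4[19] = float(data.min())
    f4[20] = float(data.max())
    f4[21] = float(data.mean())
    i4[22] = 1 if is_volume else 0  # ispg
    header[208:212] = np.frombuffer(b"MAP ", dtype=np.uint8)
    header[212:216] = np.frombuffer(bytes([0x44, 0x44, 0, 0]), dtype=np.uint8)
    f4[54] = float(data.std())  # rms
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path):
    """Read an MRC2014 mode-2 file.

    Returns ``(data, pixel_size, is_volume)``; 2D data is returned as (ny, nx),
    stacks/volumes as (nz, ny, nx).  Unsupported modes and truncated files
    raise ``ValueError`` without returning partial data.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise ValueError(f"{path}: truncated MRC header ({len(header)} bytes)")
        h = np.frombuffer(header, dtype=np.uint8)
        i4 = h.view("<i4")
        f4 = h.view("<f4")
        nx, ny, nz = (int(v) for v in i4[0:3])
        mode = int(i4[3])
        if mode != 2:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2 is supported)")
        mx = int(i4[7])
        pixel_size = float(f4[10]) / mx if mx > 0 else 1.0
        is_volume = int(i4[22]) != 0
        expected = nx * ny * nz * 4
        raw = fh.read(expected)
        if len(raw) < expected:
            raise ValueError(
                f"{path}: truncated MRC data ({len(raw)} of {expected} bytes)"
            )
        data = np.frombuffer(raw, dtype="<f4").reshape(nz, ny, nx).astype(np.float32)
    if nz == 1:
        return data[0], pixel_size, False
    return data, pixel_size, is_volume
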