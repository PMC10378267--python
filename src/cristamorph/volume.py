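"""3-D grayscale volumes with physical voxel size, and MRC 2014 file I/O.

A tomographic reconstruction is held as a ``Volume``: a ``(z, y, x)``
``float32`` array plus an isotropic voxel size in nanometres.  Physical
coordinates are voxel-centre coordinates, ``index * voxel_size``, with z the
slab normal.

The MRC reader/writer below covers the subset of the MRC 2014 standard that
tomography pipelines actually exchange: modes 0 (int8), 1 (int16) and
2 (float32), single-volume files, either byte order.  Cell dimensions in the
header are in Angstrom per MRC convention and are converted to nm on read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Volume", "read_mrc", "write_mrc"]

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32}


@dataclass
class Volume:
    """A 3-D grayscale grid with physical voxel size.

    Parameters
    ----------
    data:
        ``(nz, ny, nx)`` array; converted to float32.
    voxel_size:
        Isotropic voxel edge length in nm.
    """

    data: np.ndarray
    voxel_size: float = 1.8

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size)

    def physical_extent(self) -> tuple[float, float, float]:
        """Slab extent (z, y, x) in nm."""
        nz, ny, nx = self.data.shape
        return (nz * self.voxel_size, ny * self.voxel_size, nx * self.voxel_size)


def _parse_header(raw: bytes) -> dict:
    # words 1-3: nx ny nz (columns, rows, sections); word 4: mode
    machst = raw[212:216]
    # MAP magic at word 53; machine stamp distinguishes endianness
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ValueError("not an MRC file (missing MAP magic)")
    little = machst[0] in (0x44, 0x00)  # 0x44 0x44/0x41 = little endian
    fmt = "<" if little else ">"
    nx, ny, nz, mode = struct.unpack(fmt + "4i", raw[0:16])
    mx, my, mz = struct.unpack(fmt + "3i", raw[28:40])
    xlen, ylen, zlen = struct.unpack(fmt + "3f", raw[40:52])
    nsymbt = struct.unpack(fmt + "i", raw[92:96])[0]
    return {
        "nx": nx, "ny": ny, "nz": nz, "mode": mode,
        "mx": mx, "my": my, "mz": mz,
        "xlen": xlen, "ylen": ylen, "zlen": zlen,
        "nsymbt": nsymbt, "byteorder": fmt,
    }


def read_mrc(path: str | Path) -> Volume:
    """Read an MRC volume (modes 0/1/2), returning intensities as float32.

    The voxel size is taken from the header cell dimensions (Angstrom, per
    MRC convention) divided by the grid sampling, and converted to nm.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise ValueError(f"{path}: truncated MRC file ({len(raw)} bytes)")
    h = _parse_header(raw[:_HEADER_BYTES])
    if h["mode"] not in _MODE_DTYPES:
        raise ValueError(f"{path}: unsupported MRC mode {h['mode']}")
    dtype = np.dtype(_MODE_DTYPES[h["mode"]]).newbyteorder(h["byteorder"])
    count = h["nx"] * h["ny"] * h["nz"]
    offset = _HEADER_BYTES + h["nsymbt"]
    expected = offset + count * dtype.itemsize
    if len(raw) < expected:
        raise ValueError(
            f"{path}: truncated data block ({len(raw)} bytes, expected {expected})"
        )
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=offset)
    data = data.reshape(h["nz"], h["ny"], h["nx"])
    if h["mx"] > 0 and h["xlen"] > 0:
        voxel_nm = (h["xlen"] / h["mx"]) / 10.0  # Angstrom -> nm
    else:
        voxel_nm = 1.8
    return Volume(np.ascontiguousarray(data, dtype=np.float32), voxel_nm)


def write_mrc(vol: Volume, path: str | Path, mode: int = 2) -> None:
    """Write a Volume as little-endian MRC 2014 (mode 2 by default).

    Modes 0/1 quantize to int8/int16 after clipping to the dtype range;
    mode 2 round-trips float32 bit-identically.
    """
    if mode not in _MODE_DTYPES:
        raise ValueError(f"unsupported MRC mode {mode}")
    nz, ny, nx = vol.data.shape
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    if mode == 2:
        data = vol.data.astype(dtype)
    else:
        info = np.iinfo(_MODE_DTYPES[mode])
        data = np.clip(np.rint(vol.data), info.min, info.max).astype(dtype)

    cell_ang = (nx * vol.voxel_size * 10.0, ny * vol.voxel_size * 10.0,
                nz * vol.voxel_size * 10.0)
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)          # nxstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)        # mx my mz
    struct.pack_into("<3f", header, 40, *cell_ang)         # cella (Angstrom)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)           # mapc mapr maps
    dmin, dmax = float(vol.data.min()), float(vol.data.max())
    struct.pack_into("<3f", header, 76, dmin, dmax, float(vol.data.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)              # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))      # little-endian stamp
    struct.pack_into("<f", header, 216, float(vol.data.std()))
    struct.pack_into("<i", header, 220, 1)                 # nlabl
    label = b"cristamorph" + b" " * (80 - len(b"cristamorph"))
    header[224:304] = label
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())
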