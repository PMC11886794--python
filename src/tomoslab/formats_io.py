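"""Tilt-series and volume I/O: MRC2014 stacks/volumes, TLT/RAWTLT angle files.

The on-disk axis order follows the MRC convention (section, row, column),
i.e. ``(tilt, y, x)`` for stacks and ``(z, y, x)`` for volumes, and all
in-memory arrays keep that order so no transposes happen at the I/O
boundary.  Integer MRC modes (0, 1, 6) are promoted to float32 on read;
output is always mode 2 (float32).  ``.st`` files are treated as an MRC
dialect.  TLT and RAWTLT files are plain text with one tilt angle in
degrees per non-blank line and are parsed identically.
"""

from __future__ import annotations

import os
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TiltSeries",
    "Volume",
    "MRCFormatError",
    "AngleParseError",
    "AngleCountMismatchError",
    "read_tilt_series",
    "read_volume",
    "parse_angle_file",
    "write_angle_file",
    "write_volume",
    "write_tilt_series",
]

_HEADER_SIZE = 1024
_MAP_MAGIC = b"MAP "
# MRC mode -> numpy dtype (little-endian); only real modes are supported.
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MRCFormatError(ValueError):
    """The file is not a readable MRC/ST stack or volume."""


class AngleParseError(ValueError):
    """A tilt-angle file contains a non-numeric token."""


class AngleCountMismatchError(ValueError):
    """Number of angles does not match the number of stack sections."""


@dataclass
class TiltSeries:
    """An ordered stack of aligned 2D projections with per-image tilt angles.

    Parameters
    ----------
    images : ndarray, shape (n_tilts, n_rows, n_cols)
        Projection images; rows run along y (the tilt axis), columns along x.
    angles_deg : ndarray, shape (n_tilts,)
        Nominal stage tilt angle of each image, degrees.
    pixel_size_nm : float or None
        Detector pixel size in nanometres; ``None`` when unknown.
    """

    images: np.ndarray
    angles_deg: np.ndarray
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ValueError(f"images must be 3D (n_tilts, ny, nx), got shape {self.images.shape}")
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64).ravel()
        if self.images.shape[0] != self.angles_deg.size:
            raise AngleCountMismatchError(
                f"{self.images.shape[0]} sections but {self.angles_deg.size} angles"
            )
        if self.angles_deg.size < 1:
            raise ValueError("a tilt series needs at least one image")
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("tilt angles must be finite")
        if np.unique(self.angles_deg).size < self.angles_deg.size:
            warnings.warn("duplicate tilt angles in series", stacklevel=3)
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive or None")

    @property
    def n_tilts(self) -> int:
        return self.images.shape[0]

    @property
    def det_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of each projection image."""
        return self.images.shape[1], self.images.shape[2]

    @property
    def angles_rad(self) -> np.ndarray:
        return np.deg2rad(self.angles_deg)


@dataclass
class Volume:
    """A 3D density grid in (z, y, x) order with a center-based origin."""

    data: np.ndarray
    voxel_size_nm: float | None = None
    coverage: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D (nz, ny, nx), got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if self.voxel_size_nm is not None and not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be positive or None")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def parse_angle_file(path: str | os.PathLike) -> list[float]:
    """Parse a TLT/RAWTLT file: one angle in degrees per non-blank line.

    Returns angles in file order.  Raises :class:`AngleParseError` (naming
    the offending line) on a non-numeric token.
    """
    angles: list[float] = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                angles.append(float(token))
            except ValueError:
                raise AngleParseError(
                    f"{os.fspath(path)}: line {lineno}: not a number: {token!r}"
                ) from None
    return angles


def write_angle_file(angles_deg, path: str | os.PathLike) -> None:
    """Write angles (degrees) one per line, TLT style."""
    with open(path, "w", encoding="ascii") as fh:
        for a in np.asarray(angles_deg, dtype=np.float64).ravel():
            fh.write(f"{a:.6g}\n")


# ---------------------------------------------------------------------------
# MRC2014 header handling.  The header is 1024 bytes of mostly int32/float32
# words; only the words this package needs are interpreted, the rest are
# preserved as zeros on write.


def _read_header(raw: bytes) -> dict:
    if len(raw) < _HEADER_SIZE:
        raise MRCFormatError("file shorter than the 1024-byte MRC header")

    def parse(order: str) -> dict:
        nx, ny, nz, mode = struct.unpack(order + "4i", raw[0:16])
        mx, my, mz = struct.unpack(order + "3i", raw[28:40])
        xlen, ylen, zlen = struct.unpack(order + "3f", raw[40:52])
        dmin, dmax, dmean = struct.unpack(order + "3f", raw[76:88])
        ispg, nsymbt = struct.unpack(order + "2i", raw[88:96])
        return {
            "nx": nx, "ny": ny, "nz": nz, "mode": mode,
            "mx": mx, "my": my, "mz": mz,
            "xlen": xlen, "ylen": ylen, "zlen": zlen,
            "dmin": dmin, "dmax": dmax, "dmean": dmean,
            "ispg": ispg, "nsymbt": nsymbt,
            "byte_order": order,
        }

    hdr = parse("<")
    plausible = (
        hdr["mode"] in _MODE_DTYPES
        and 0 < hdr["nx"] < 100_000
        and 0 < hdr["ny"] < 100_000
        and 0 < hdr["nz"] < 100_000
    )
    if not plausible:
        hdr_be = parse(">")
        plausible_be = (
            hdr_be["mode"] in _MODE_DTYPES
            and 0 < hdr_be["nx"] < 100_000
            and 0 < hdr_be["ny"] < 100_000
            and 0 < hdr_be["nz"] < 100_000
        )
        if not plausible_be:
            raise MRCFormatError(
                f"unreadable MRC header (mode={hdr['mode']}, "
                f"dims=({hdr['nx']},{hdr['ny']},{hdr['nz']}))"
            )
        hdr = hdr_be
    if hdr["nsymbt"] < 0:
        raise MRCFormatError("negative extended-header size")
    return hdr


def _pack_header(
    shape_zyx: tuple[int, int, int],
    mode: int,
    voxel_size_nm: float | None,
    dmin: float,
    dmax: float,
    dmean: float,
    rms: float,
    ispg: int,
    label: str,
) -> bytes:
    nz, ny, nx = shape_zyx
    hdr = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", hdr, 0, nx, ny, nz, mode)
    # nxstart/nystart/nzstart stay 0; mx,my,mz mirror the grid size.
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)
    apix_ang = (voxel_size_nm or 0.0) * 10.0  # cell lengths are Angstroms
    struct.pack_into("<3f", hdr, 40, nx * apix_ang, ny * apix_ang, nz * apix_ang)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into("<3f", hdr, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", hdr, 88, ispg, 0)  # ispg, nsymbt
    struct.pack_into("<i", hdr, 108, 20140)  # NVERSION
    hdr[208:212] = _MAP_MAGIC
    hdr[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", hdr, 216, rms)
    struct.pack_into("<i", hdr, 220, 1)  # nlabl
    hdr[224:224 + 80] = label.encode("ascii", "replace")[:80].ljust(80)
    return bytes(hdr)


def _read_mrc(path: str | os.PathLike) -> tuple[np.ndarray, float | None]:
    """Read any supported MRC/ST file; returns (float32 (nz,ny,nx), voxel nm)."""
    with open(path, "rb") as fh:
        raw_hdr = fh.read(_HEADER_SIZE)
        hdr = _read_header(raw_hdr)
        fh.seek(_HEADER_SIZE + hdr["nsymbt"])
        dtype = np.dtype(_MODE_DTYPES[hdr["mode"]]).newbyteorder(hdr["byte_order"])
        count = hdr["nx"] * hdr["ny"] * hdr["nz"]
        data = np.fromfile(fh, dtype=dtype, count=count)
    if data.size != count:
        raise MRCFormatError(
            f"truncated data block: expected {count} values, got {data.size}"
        )
    data = data.reshape(hdr["nz"], hdr["ny"], hdr["nx"]).astype(np.float32)
    voxel_nm = None
    if hdr["mx"] > 0 and hdr["xlen"] > 0:
        voxel_nm = hdr["xlen"] / hdr["mx"] / 10.0
    return data, voxel_nm


def _write_mrc(
    data: np.ndarray,
    path: str | os.PathLike,
    voxel_size_nm: float | None,
    ispg: int,
    label: str,
    mode: int = 2,
) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite values to MRC")
    out = np.ascontiguousarray(data, dtype=np.dtype(_MODE_DTYPES[mode]))
    stats = out.astype(np.float64)
    hdr = _pack_header(
        out.shape,
        mode,
        voxel_size_nm,
        float(stats.min()),
        float(stats.max()),
        float(stats.mean()),
        float(stats.std()),
        ispg,
        label,
    )
    with open(path, "wb") as fh:
        fh.write(hdr)
        out.tofile(fh)


def read_tilt_series(
    path: str | os.PathLike, angles_path: str | os.PathLike
) -> TiltSeries:
    """Read an MRC/ST stack plus a TLT/RAWTLT angle file.

    Section ``i`` of the stack pairs with line ``i`` of the angle file.
    Raises :class:`AngleCountMismatchError` if the counts disagree and
    :class:`MRCFormatError` on an unreadable header.
    """
    data, voxel_nm = _read_mrc(path)
    angles = parse_angle_file(angles_path)
    if len(angles) != data.shape[0]:
        raise AngleCountMismatchError(
            f"{os.fspath(path)} has {data.shape[0]} sections but "
            f"{os.fspath(angles_path)} has {len(angles)} angles"
        )
    return TiltSeries(images=data, angles_deg=np.asarray(angles), pixel_size_nm=voxel_nm)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read an MRC volume as float32 (z, y, x)."""
    data, voxel_nm = _read_mrc(path)
    return Volume(data=data, voxel_size_nm=voxel_nm)


def write_volume(vol: Volume, path: str | os.PathLike) -> None:
    """Write a volume as MRC mode 2 with min/max/mean/rms header statistics."""
    _write_mrc(vol.data, path, vol.voxel_size_nm, ispg=1, label="tomoslab volume")


def write_tilt_series(ts: TiltSeries, path: str | os.PathLike,
                      angles_path: str | os.PathLike | None = None) -> None:
    """Write a tilt series as an MRC/ST stack, optionally with its TLT file."""
    _write_mrc(ts.images, path, ts.pixel_size_nm, ispg=0, label="tomoslab tilt series")
    if angles_path is not None:
        write_angle_file(ts.angles_deg, angles_path)
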