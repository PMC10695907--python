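"""Volumetric image containers and file I/O.

Volumes are 3D grayscale scalar fields stored in ``(z, y, x)`` axis order,
where ``z`` is the slice index of the acquisition stack.  Voxels are
isotropic; the single edge length is carried in micrometres.  Two on-disk
formats are supported and round-trip bit-exactly:

* multi-page TIFF (slices along ``z``), with the voxel edge length recorded
  as JSON in the ImageDescription tag, and
* raw binary plus a small key-value sidecar text file (``<path>.meta``)
  giving dimensions, dtype, byte order and voxel edge length.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "VoxelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "VolumeIOError",
]

#: dtypes accepted for grayscale volumes, keyed by bit depth
_SUPPORTED_DTYPES = {
    np.dtype(np.uint8): 8,
    np.dtype(np.uint16): 16,
    np.dtype(np.uint32): 32,
    np.dtype(np.float32): 32,
}


class VolumeIOError(IOError):
    """Raised for malformed, inconsistent or unsupported volume files."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D grayscale scalar field with isotropic voxel size.

    Parameters
    ----------
    data : numpy.ndarray
        3D array in ``(z, y, x)`` order; dtype uint8, uint16, uint32 or
        float32.
    voxel_edge_um : float
        Isotropic voxel edge length in micrometres (> 0).
    """

    data: np.ndarray
    voxel_edge_um: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if self.data.dtype not in _SUPPORTED_DTYPES:
            raise ValueError(
                f"unsupported dtype {self.data.dtype}; expected one of "
                f"{sorted(str(d) for d in _SUPPORTED_DTYPES)}"
            )
        if not self.voxel_edge_um > 0:
            raise ValueError(f"voxel_edge_um must be > 0, got {self.voxel_edge_um}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def dtype_bits(self) -> int:
        return _SUPPORTED_DTYPES[self.data.dtype]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean 3D field on the same grid conventions as :class:`VoxelVolume`."""

    data: np.ndarray
    voxel_edge_um: float

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if self.data.dtype != np.bool_:
            raise ValueError(f"mask dtype must be bool, got {self.data.dtype}")
        if not self.voxel_edge_um > 0:
            raise ValueError(f"voxel_edge_um must be > 0, got {self.voxel_edge_um}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# raw + sidecar format

_SIDECAR_SUFFIX = ".meta"

_DTYPE_NAMES = {"uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32,
                "float32": np.float32}


def _sidecar_path(path: str) -> str:
    return path + _SIDECAR_SUFFIX


def _write_raw(vol: VoxelVolume, path: str) -> None:
    data = np.ascontiguousarray(vol.data)
    data.tofile(path)
    nz, ny, nx = vol.dims
    lines = [
        f"dims: {nz} {ny} {nx}",
        f"dtype: {data.dtype.name}",
        "byte_order: little",
        f"voxel_edge_um: {vol.voxel_edge_um!r}",
    ]
    with open(_sidecar_path(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _read_sidecar(path: str) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise VolumeIOError(f"malformed sidecar line in {path!r}: {line!r}")
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    return meta


def _read_raw(path: str) -> VoxelVolume:
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise VolumeIOError(f"raw volume {path!r} has no sidecar {sidecar!r}")
    meta = _read_sidecar(sidecar)
    for key in ("dims", "dtype", "voxel_edge_um"):
        if key not in meta:
            raise VolumeIOError(f"sidecar {sidecar!r} is missing key {key!r}")
    try:
        dims = tuple(int(t) for t in meta["dims"].split())
    except ValueError as exc:
        raise VolumeIOError(f"bad dims in sidecar {sidecar!r}: {meta['dims']!r}") from exc
    if len(dims) != 3 or min(dims) < 1:
        raise VolumeIOError(f"dims must be three positive integers, got {dims}")
    if meta["dtype"] not in _DTYPE_NAMES:
        raise VolumeIOError(f"unsupported dtype {meta['dtype']!r} in sidecar {sidecar!r}")
    dtype = np.dtype(_DTYPE_NAMES[meta["dtype"]])
    if meta.get("byte_order", "little") == "big":
        dtype = dtype.newbyteorder(">")
    raw = np.fromfile(path, dtype=dtype)
    expected = dims[0] * dims[1] * dims[2]
    if raw.size != expected:
        raise VolumeIOError(
            f"raw file {path!r} holds {raw.size} voxels but sidecar dims "
            f"{dims} imply {expected}"
        )
    data = raw.reshape(dims).astype(dtype.newbyteorder("="), copy=False)
    return VoxelVolume(data=data, voxel_edge_um=float(meta["voxel_edge_um"]))


# ---------------------------------------------------------------------------
# TIFF format


def _write_tiff(vol: VoxelVolume, path: str) -> None:
    description = json.dumps({"voxel_edge_um": vol.voxel_edge_um})
    tifffile.imwrite(path, vol.data, description=description, metadata=None,
                     photometric="minisblack")


def _read_tiff(path: str, voxel_edge_um: float | None) -> VoxelVolume:
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise VolumeIOError(
                f"TIFF {path!r} has slices of differing shapes: {sorted(shapes)}"
            )
        data = tif.asarray()
        description = tif.pages[0].description
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise VolumeIOError(f"TIFF {path!r} is not a grayscale slice stack")
    if data.dtype not in _SUPPORTED_DTYPES:
        raise VolumeIOError(f"TIFF {path!r} has unsupported dtype {data.dtype}")
    if voxel_edge_um is None:
        try:
            voxel_edge_um = float(json.loads(description)["voxel_edge_um"])
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            raise VolumeIOError(
                f"TIFF {path!r} carries no voxel_edge_um metadata; pass "
                "voxel_edge_um explicitly to override"
            ) from None
    return VoxelVolume(data=data, voxel_edge_um=float(voxel_edge_um))


# ---------------------------------------------------------------------------
# public API


def read_volume(path: str, voxel_edge_um: float | None = None) -> VoxelVolume:
    """Read a grayscale volume from a TIFF stack or a raw + sidecar pair.

    Parameters
    ----------
    path : str
        ``.tif``/``.tiff`` for a slice stack, anything else is treated as raw
        binary with a ``<path>.meta`` sidecar.
    voxel_edge_um : float, optional
        Overrides (TIFF) or replaces missing voxel-size metadata.

    Returns
    -------
    VoxelVolume
        Volume with ``data[z]`` equal to slice ``z`` of the stack.
    """
    if not os.path.exists(path):
        raise VolumeIOError(f"no such volume file: {path!r}")
    if path.lower().endswith((".tif", ".tiff")):
        return _read_tiff(path, voxel_edge_um)
    vol = _read_raw(path)
    if voxel_edge_um is not None:
        vol = VoxelVolume(data=vol.data, voxel_edge_um=float(voxel_edge_um))
    return vol


def write_volume(vol: VoxelVolume, path: str) -> None:
    """Write a volume to TIFF (by extension) or raw + sidecar."""
    if path.lower().endswith((".tif", ".tiff")):
        _write_tiff(vol, path)
    else:
        _write_raw(vol, path)


def write_mask(mask: BinaryMask, path: str) -> None:
    """Write a binary mask as a 0/1-valued 8-bit volume."""
    vol = VoxelVolume(data=mask.data.astype(np.uint8),
                      voxel_edge_um=mask.voxel_edge_um)
    write_volume(vol, path)


def read_mask(path: str, voxel_edge_um: float | None = None) -> BinaryMask:
    """Read a mask previously written with :func:`write_mask` (nonzero = foreground)."""
    vol = read_volume(path, voxel_edge_um=voxel_edge_um)
    return BinaryMask(data=vol.data > 0, voxel_edge_um=vol.voxel_edge_um)
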