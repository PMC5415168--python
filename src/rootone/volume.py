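"""Calibrated 3-D greyscale and binary volumes, with TIFF / raw I/O.

Index order is ``(z, y, x)`` throughout the package: axis 0 walks down the
soil column (slice 0 is the top of the pot), axis 1 is the image row and
axis 2 the image column.  Voxels are isotropic with a physical side length
in micrometres.

Supported on-disk containers:

* multi-page greyscale TIFF (8-, 16-bit unsigned or 32-bit float), plus a
  JSON sidecar ``<file>.json`` carrying the voxel size;
* little-endian raw binary with a mandatory JSON sidecar
  ``{"dims": [z, y, x], "dtype": ..., "voxel_size_um": ...}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import VolumeError

#: dtype -> nominal bit depth of the container
_SUPPORTED_DTYPES = {
    np.dtype("uint8"): 8,
    np.dtype("uint16"): 16,
    np.dtype("float32"): 32,
}


@dataclass
class Volume:
    """A calibrated 3-D greyscale grid.

    Parameters
    ----------
    data:
        3-D array indexed ``(z, y, x)``.  ``uint8``, ``uint16`` or
        ``float32`` (``float64`` input is down-cast to ``float32``).
    voxel_size_um:
        Isotropic voxel side length in micrometres, > 0.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.dtype == np.float64:
            arr = arr.astype(np.float32)
        if arr.ndim != 3:
            raise VolumeError(f"volume data must be 3-D, got {arr.ndim}-D")
        if arr.dtype not in _SUPPORTED_DTYPES:
            raise VolumeError(f"unsupported bit depth / dtype {arr.dtype}")
        if min(arr.shape) < 1:
            raise VolumeError("all volume dimensions must be >= 1")
        if not self.voxel_size_um > 0:
            raise VolumeError("voxel_size_um must be positive")
        if arr.dtype.kind == "f" and not np.all(np.isfinite(arr)):
            raise VolumeError("grey values must be finite")
        self.data = arr
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def bit_depth(self) -> int:
        return _SUPPORTED_DTYPES[self.data.dtype]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryVolume:
    """A calibrated 3-D binary grid (stored as booleans)."""

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeError(f"binary volume must be 3-D, got {arr.ndim}-D")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise VolumeError("binary volume may only contain {0, 1}")
            arr = arr.astype(bool)
        if min(arr.shape) < 1:
            raise VolumeError("all volume dimensions must be >= 1")
        if not self.voxel_size_um > 0:
            raise VolumeError("voxel_size_um must be positive")
        self.data = arr
        self.voxel_size_um = float(self.voxel_size_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_stack(volume: Volume | BinaryVolume, path) -> None:
    """Write a volume as a multi-page TIFF or raw binary plus JSON sidecar.

    Binary volumes are stored as ``uint8`` with values {0, 1} and flagged in
    the sidecar.  Round-trips are lossless for integer depths.
    """
    path = Path(path)
    is_binary = isinstance(volume, BinaryVolume)
    data = volume.data.astype(np.uint8) if is_binary else volume.data
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, data, photometric="minisblack")
        else:
            data.tofile(path)
    except OSError as exc:
        raise VolumeError(f"cannot write volume to {path}: {exc}") from exc
    meta = {
        "dims": list(data.shape),
        "dtype": data.dtype.name,
        "voxel_size_um": volume.voxel_size_um,
        "binary": is_binary,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path, voxel_size_um: float | None = None) -> Volume:
    """Read a multi-page TIFF or raw-binary volume.

    The voxel size is taken from the explicit argument when given, otherwise
    from the JSON sidecar written by :func:`write_stack`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such file: {path}")

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise VolumeError("inconsistent slice shape across TIFF pages")
            data = tif.asarray()
        if data.ndim == 2:  # single-slice file
            data = data[np.newaxis]
    else:
        if not {"dims", "dtype"} <= meta.keys():
            raise VolumeError(f"raw volume {path} needs a JSON sidecar with dims/dtype")
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        data = data.reshape(meta["dims"])

    vs = voxel_size_um if voxel_size_um is not None else meta.get("voxel_size_um")
    if vs is None:
        raise VolumeError(f"no voxel size given and no sidecar for {path}")
    return Volume(data, float(vs))


def read_binary_stack(path, voxel_size_um: float | None = None) -> BinaryVolume:
    """Read a volume written from a :class:`BinaryVolume` (or any 0/1 stack)."""
    vol = read_stack(path, voxel_size_um)
    return BinaryVolume(vol.data > 0, vol.voxel_size_um)


def convert_to_16bit(volume: Volume, range_lo: float, range_hi: float) -> Volume:
    """Linearly rescale a grey-value window onto the full 16-bit range.

    ``range_lo`` maps to 0 and ``range_hi`` to 65535; values outside the
    window clip to the nearest bound.  Rounding is round-half-up.  This is
    the conversion applied to 32-bit reconstructions before normalization,
    pinning successive scans of one column to a common grey scale.
    """
    if not range_hi > range_lo:
        raise VolumeError("degenerate grey range: range_hi must exceed range_lo")
    x = (volume.data.astype(np.float64) - range_lo) * (65535.0 / (range_hi - range_lo))
    out = np.clip(np.floor(x + 0.5), 0.0, 65535.0).astype(np.uint16)
    return Volume(out, volume.voxel_size_um)


def dpi_to_um(dpi: float) -> float:
    """Pixel side length in micrometres for a scanner resolution in dots/inch.

    E.g. a 600 dpi flatbed scan has ~42 μm pixels.
    """
    if not dpi > 0:
        raise VolumeError("dpi must be positive")
    return 25400.0 / dpi
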