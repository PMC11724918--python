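"""Multi-page TIFF I/O for intensity and label volumes.

TIFF resolution metadata is honoured when present but a config-supplied
spacing always wins — microscopy TIFF metadata is notoriously unreliable.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .volumes import IntensityVolume, LabelVolume

__all__ = ["read_volume", "write_volume"]


def _uint_dtype_for(max_label: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValueError(f"label {max_label} exceeds 64-bit unsigned range")


def _spacing_from_tiff(tif: tifffile.TiffFile):
    """Best-effort (z, y, x) spacing in um from TIFF/ImageJ tags; None if absent."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is None or yres is None:
            return None
        xr = xres.value[0] / xres.value[1]
        yr = yres.value[0] / yres.value[1]
        if xr <= 0 or yr <= 0:
            return None
        sx, sy = 1.0 / xr, 1.0 / yr
        sz = 1.0
        ij = tif.imagej_metadata
        if ij and "spacing" in ij:
            sz = float(ij["spacing"])
        return (sz, sy, sx)
    except Exception:
        return None


def read_volume(path, kind: str, spacing=None):
    """Read a multi-page TIFF as an :class:`IntensityVolume` or :class:`LabelVolume`.

    Parameters
    ----------
    path
        File path of a multi-page TIFF (one page per z-plane).
    kind
        ``"intensity"`` or ``"label"``.  Label files must hold integer
        values exactly; any fractional value is a hard error.
    spacing
        Optional (z, y, x) voxel size override in um; takes precedence
        over TIFF metadata.
    """
    if kind not in ("intensity", "label"):
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta_spacing = _spacing_from_tiff(tif)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"expected a single-channel z-stack, got shape {data.shape}")
    sp = spacing if spacing is not None else (meta_spacing or (1.0, 1.0, 1.0))
    if kind == "label":
        return LabelVolume(data, sp)  # raises on non-integer values
    return IntensityVolume(data, sp)


def write_volume(vol, path) -> None:
    """Write a volume as a multi-page TIFF, one page per z-plane.

    Labels are stored as the narrowest unsigned integer type holding the
    maximum label; intensities as float32.  Voxel spacing is recorded in
    the TIFF resolution tags and ImageJ ``spacing`` field.
    """
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    sz, sy, sx = vol.spacing
    if isinstance(vol, LabelVolume):
        max_label = int(vol.data.max()) if vol.data.size else 0
        data = vol.data.astype(_uint_dtype_for(max_label))
    elif isinstance(vol, IntensityVolume):
        data = vol.data  # keep native float width so round-trips are lossless
    else:
        raise TypeError(f"expected IntensityVolume or LabelVolume, got {type(vol)}")
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(1.0 / sx, 1.0 / sy),
        imagej=data.dtype in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )
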