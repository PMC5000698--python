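"""Raster and CSV I/O for Mueller images and matrices.

Two on-disk layouts are supported:

``multi-page``
    A 16-page TIFF, one page per element, row-major m11..m44.
``4x4-mosaic``
    A single raster tiling the 16 planes into a 4x4 grid, row-major, so the
    full image is ``(4H, 4W)``.  TIFF for float data; PNG for integer data.

Metadata (wavelength, pixel pitch, element order, layout) travels in a JSON
sidecar ``<path>.json``; the validity mask, when not all-true, is written as
a single-page uint8 TIFF ``<stem>.mask.tif`` next to the image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .mueller import ELEMENT_NAMES, MuellerImage, MuellerMatrix

__all__ = [
    "read_mueller_image",
    "write_mueller_image",
    "read_mueller_csv",
    "write_mueller_csv",
]

LAYOUTS = ("multi-page", "4x4-mosaic")


class FormatError(ValueError):
    """Raised when an on-disk file does not match the requested layout."""


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _mask_path(path: Path) -> Path:
    return path.with_name(path.stem + ".mask.tif")


def write_mueller_image(
    path: str | Path, img: MuellerImage, layout: str = "multi-page"
) -> None:
    """Write a MuellerImage with its JSON sidecar (and mask file if needed)."""
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    if layout == "multi-page":
        tifffile.imwrite(path, img.planes, photometric="minisblack")
    else:
        h, w = img.shape
        mosaic = np.zeros((4 * h, 4 * w), dtype=img.planes.dtype)
        for k in range(16):
            r, c = divmod(k, 4)
            mosaic[r * h : (r + 1) * h, c * w : (c + 1) * w] = img.planes[k]
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio

            if not np.issubdtype(mosaic.dtype, np.integer):
                raise ValueError("PNG mosaic requires an integer dtype")
            iio.imwrite(path, mosaic)
        else:
            tifffile.imwrite(path, mosaic, photometric="minisblack")
    meta = {
        "layout": layout,
        "element_order": list(ELEMENT_NAMES),
        "shape": list(img.shape),
        "wavelength_nm": img.wavelength_nm,
        "pixel_pitch": img.pixel_pitch,
        "meta": img.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    if not img.mask.all():
        tifffile.imwrite(_mask_path(path), img.mask.astype(np.uint8))


def read_mueller_image(path: str | Path, layout: str = "multi-page") -> MuellerImage:
    """Read a MuellerImage written by :func:`write_mueller_image`.

    Raises
    ------
    FormatError
        If the plane count / tiling does not match the requested layout.
    """
    path = Path(path)
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    meta: dict = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if layout == "multi-page":
        planes = tifffile.imread(path)
        if planes.ndim == 2:
            planes = planes[None]
        if planes.shape[0] != 16:
            raise FormatError(
                f"{path} has {planes.shape[0]} planes; layout 'multi-page' "
                "requires a 16-page stack m11..m44"
            )
    else:
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio

            mosaic = np.asarray(iio.imread(path))
        else:
            mosaic = tifffile.imread(path)
        if mosaic.ndim != 2 or mosaic.shape[0] % 4 or mosaic.shape[1] % 4:
            raise FormatError(
                f"{path} shape {mosaic.shape} is not a 4x4 tiling; layout "
                "'4x4-mosaic' requires a (4H, 4W) raster"
            )
        h, w = mosaic.shape[0] // 4, mosaic.shape[1] // 4
        planes = np.stack(
            [
                mosaic[r * h : (r + 1) * h, c * w : (c + 1) * w]
                for r in range(4)
                for c in range(4)
            ]
        )
    mask = None
    mp = _mask_path(path)
    if mp.exists():
        mask = tifffile.imread(mp).astype(bool)
    return MuellerImage(
        planes=planes,
        mask=mask,
        wavelength_nm=meta.get("wavelength_nm"),
        pixel_pitch=meta.get("pixel_pitch"),
        meta=meta.get("meta", {}),
    )


def write_mueller_csv(path: str | Path, M: MuellerMatrix) -> None:
    """Write a single 4x4 Mueller matrix as a headerless CSV."""
    np.savetxt(path, M.m, delimiter=",", fmt="%.17g")


def read_mueller_csv(path: str | Path) -> MuellerMatrix:
    arr = np.loadtxt(path, delimiter=",")
    return MuellerMatrix(np.asarray(arr, dtype=float).reshape(4, 4))
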