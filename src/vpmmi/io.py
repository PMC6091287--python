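"""Raster, landmark and transform readers and writers.

External formats: single-channel PNG/TIFF images, PNG masks with 0/255
semantics, headered ``x,y`` CSV landmark files, and 3-line whitespace
separated plain-text transform matrices (diffable, full float precision).
"""

from __future__ import annotations

import logging
import os

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import (
    DEFAULT_PIXEL_SIZE,
    MODALITY_PIXEL_SIZE,
    Affine2D,
    FormatError,
    Image2D,
    InputError,
    LandmarkTriplet,
    Mask2D,
)

log = logging.getLogger("vpmmi")

_MIN_SIDE = 8


def _read_raster(path) -> np.ndarray:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any backend failure
        raise FormatError(f"unreadable image file {path}: {exc}") from exc
    if arr.ndim == 3:
        # accept gray stored as RGB(A) with identical channels; anything with
        # genuinely differing channels has no defined conversion rule
        rgb = arr[..., :3]
        if np.all(rgb == rgb[..., :1]):
            arr = rgb[..., 0]
        else:
            raise FormatError(f"{path}: multi-channel image without conversion rule")
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D raster, got ndim={arr.ndim}")
    return arr


def read_image(path, modality: str | None = None,
               pixel_size: tuple[float, float] | None = None) -> Image2D:
    """Read a single-channel PNG/TIFF as an :class:`Image2D`.

    ``pixel_size`` (mm, as ``(dy, dx)``) takes precedence; otherwise the
    declared ``modality`` ("CT" -> 0.32 mm, "TEE" -> 0.224 mm) sets it, and
    with neither the default 1.0 mm spacing is used.  16-bit sources are
    rescaled to [0, 255] with a logged warning.
    """
    raw = _read_raster(path)
    arr = raw.astype(np.float64)
    if raw.dtype == np.uint16 or arr.max() > 255.0:
        log.warning("%s: >8-bit intensities, rescaling to [0, 255]", path)
        scale = 65535.0 if raw.dtype == np.uint16 else float(arr.max())
        arr = arr * (255.0 / scale)
    if arr.min() < 0:
        raise FormatError(f"{path}: negative intensities are not valid for ingest")
    h, w = arr.shape
    if h < _MIN_SIDE or w < _MIN_SIDE:
        raise FormatError(f"{path}: image must be at least {_MIN_SIDE}x{_MIN_SIDE}")
    if pixel_size is None:
        if modality is not None:
            try:
                pixel_size = MODALITY_PIXEL_SIZE[modality.upper()]
            except KeyError:
                raise InputError(f"unknown modality {modality!r}") from None
        else:
            pixel_size = DEFAULT_PIXEL_SIZE
    return Image2D(arr, pixel_size=pixel_size)


def write_image(image: Image2D, path) -> None:
    """Write an image: float32 TIFF for .tif/.tiff, clipped 8-bit PNG else."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
        iio.imwrite(path, arr)


def read_mask(path) -> Mask2D:
    """Read a 0/255 PNG mask; any value > 127 is foreground."""
    arr = _read_raster(path)
    return Mask2D(arr > (np.iinfo(arr.dtype).max // 2 if arr.dtype.kind == "u" else 0.5))


def write_mask(mask: Mask2D, path) -> None:
    iio.imwrite(str(path), (mask.bits.astype(np.uint8) * 255))


def read_landmarks(path, image: Image2D | None = None) -> LandmarkTriplet:
    """Read a headered ``x,y`` CSV of exactly three landmark points."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable landmark CSV {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if "x" not in cols or "y" not in cols:
        raise FormatError(f"{path}: landmark CSV needs 'x' and 'y' columns")
    df.columns = cols
    if len(df) != 3:
        raise InputError(f"{path}: expected exactly 3 landmark rows, got {len(df)}")
    lm = LandmarkTriplet(df[["x", "y"]].to_numpy(dtype=float))
    if image is not None:
        lm.require_within(image.shape)
    return lm


def write_landmarks(lm: LandmarkTriplet, path) -> None:
    pd.DataFrame(lm.points, columns=["x", "y"]).to_csv(path, index=False)


def write_transform(t: Affine2D, path) -> None:
    """Serialize as three whitespace-separated rows at full float precision."""
    np.savetxt(path, t.matrix, fmt="%.17g")


def read_transform(path) -> Affine2D:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        m = np.loadtxt(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable transform file {path}: {exc}") from exc
    if m.shape != (3, 3):
        raise FormatError(f"{path}: transform file must hold a 3x3 matrix")
    return Affine2D(m)
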