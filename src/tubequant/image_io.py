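"""TIFF input/output and grayscale conversion.

TIFF is the supported input format: lossy-compressed formats blunt the
high-frequency intensity changes that edge detection relies on.  Images
are handled as numpy arrays — an RGB image is an ``(H, W, 3)`` array, a
grayscale image an ``(H, W)`` float array.  Overlay outputs are written
as 8-bit RGB TIFFs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile


class UnsupportedFormatError(ValueError):
    """The file exists but is not a readable TIFF image."""


def load_image(path, permissive: bool = False) -> np.ndarray:
    """Load a TIFF as an ``(H, W, 3)`` RGB array without lossy re-encoding.

    Grayscale (single-plane) TIFFs are promoted to three identical
    planes.  An RGBA image keeps its first three channels.

    Parameters
    ----------
    path : path-like
        File to read.
    permissive : bool
        When True, fall back to Pillow for non-TIFF files (useful for
        testing with PNGs); strict TIFF-only otherwise.

    Raises
    ------
    FileNotFoundError
        *path* does not exist.
    UnsupportedFormatError
        *path* exists but cannot be decoded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        if permissive:
            try:
                from PIL import Image

                arr = np.asarray(Image.open(path))
            except Exception:
                raise UnsupportedFormatError(f"unsupported or corrupt image file: {path}") from exc
        else:
            raise UnsupportedFormatError(f"unsupported or corrupt TIFF file: {path}") from exc
    return _as_rgb(arr)


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return np.stack([arr, arr, arr], axis=-1)
    if arr.ndim == 3:
        # channel-first TIFFs (planes, H, W) are transposed
        if arr.shape[0] in (3, 4) and arr.shape[-1] not in (3, 4):
            arr = np.moveaxis(arr, 0, -1)
        if arr.shape[-1] >= 3:
            return np.ascontiguousarray(arr[..., :3])
        if arr.shape[-1] == 1:
            return np.repeat(arr, 3, axis=-1)
    raise UnsupportedFormatError(f"cannot interpret array of shape {arr.shape} as an RGB image")


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Average the three channels, then rescale to the source luminance range.

    Each output pixel is the mean of the red, green and blue values at
    that location.  The result is then linearly stretched so its min/max
    match the global min/max intensity of the source image.  A
    zero-dynamic-range image is returned unstretched (no division by
    zero).

    Returns a float64 ``(H, W)`` array.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    gray = img.mean(axis=-1)
    lo, hi = float(img.min()), float(img.max())
    glo, ghi = float(gray.min()), float(gray.max())
    if ghi > glo:
        gray = (gray - glo) * (hi - lo) / (ghi - glo) + lo
    return gray


def _as_uint8_rgb(base: np.ndarray) -> np.ndarray:
    base = _as_rgb(np.asarray(base))
    if base.dtype == np.uint8:
        return base.copy()
    b = base.astype(np.float64)
    hi = b.max()
    if hi > 255:
        lo = b.min()
        b = (b - lo) * 255.0 / (hi - lo) if hi > lo else np.zeros_like(b)
    return np.clip(np.round(b), 0, 255).astype(np.uint8)


def write_overlay(base: np.ndarray, mask: np.ndarray, color, path) -> Path:
    """Write *base* with *mask* painted in *color* as an 8-bit RGB TIFF.

    The output equals *base* wherever the mask is 0 and the overlay
    color wherever it is 1.
    """
    base8 = _as_uint8_rgb(base)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != base8.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {base8.shape[:2]}"
        )
    out = base8
    out[mask] = np.asarray(color, dtype=np.uint8)
    path = Path(path)
    tifffile.imwrite(path, out, photometric="rgb")
    return path


def write_tiff(image: np.ndarray, path) -> Path:
    """Write a grayscale or RGB array to *path* as an uncompressed TIFF."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.ndim == 3:
        tifffile.imwrite(path, arr, photometric="rgb")
    else:
        tifffile.imwrite(path, arr)
    return path
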