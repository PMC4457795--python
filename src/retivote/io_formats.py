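"""Reading and writing fundus images and binary masks.

Images are held as plain NumPy arrays: RGB rasters as float ``(H, W, 3)``
and gray / mask rasters as 2D arrays. All intensities are normalized to
``[0, 1]`` on read by dividing by the format's maximum value (255 for
8-bit, 65535 for 16-bit), so every downstream operation works on
normalized gray values. Coordinates are row-major and 0-based:
``(row, col)`` with the origin at the top-left corner.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "read_image",
    "green_channel",
    "read_mask",
    "write_mask",
    "write_gray",
    "estimate_fov",
]

_MAX_BY_DTYPE = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def _normalize(raw: np.ndarray, path: Path) -> np.ndarray:
    if raw.dtype in _MAX_BY_DTYPE:
        return raw.astype(np.float64) / _MAX_BY_DTYPE[raw.dtype]
    if np.issubdtype(raw.dtype, np.floating):
        return np.clip(raw.astype(np.float64), 0.0, 1.0)
    raise ValueError(f"unsupported bit depth {raw.dtype} in {path}")


def read_image(path) -> np.ndarray:
    """Read a fundus image (PNG/TIFF/PPM/GIF) as a float RGB array in [0, 1].

    Grayscale files are replicated to 3 channels with a warning; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.ndim == 2:
        warnings.warn(f"{path} is grayscale; replicating to 3 channels")
        raw = np.stack([raw] * 3, axis=-1)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {raw.shape} in {path}")
    if raw.shape[0] < 16 or raw.shape[1] < 16:
        raise ValueError(f"image {path} smaller than 16x16: {raw.shape[:2]}")
    return _normalize(raw, path)


def green_channel(rgb: np.ndarray) -> np.ndarray:
    """Extract the green plane (channel index 1) of an RGB raster.

    The green channel carries the best vessel/background contrast in
    fundus photographs and is the input to the enhancement front end.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB raster, got {rgb.shape}")
    return np.ascontiguousarray(rgb[:, :, 1], dtype=np.float64)


def read_mask(path, like: np.ndarray | None = None) -> np.ndarray:
    """Read a binary mask; any nonzero pixel becomes True.

    ``like`` optionally gives a reference raster whose 2D shape the mask
    must match.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    raw = iio.imread(path)
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    mask = np.asarray(raw) != 0
    if like is not None and mask.shape != np.asarray(like).shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape "
            f"{np.asarray(like).shape[:2]} ({path})"
        )
    return mask


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit 0/255 single-channel PNG."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {mask.shape}")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def write_gray(img: np.ndarray, path) -> None:
    """Write a real-valued 2D raster as a 32-bit float TIFF (intermediates)."""
    iio.imwrite(Path(path), np.asarray(img, dtype=np.float32))


def estimate_fov(
    gray: np.ndarray, threshold: float = 0.02, closing_radius: int = 5
) -> np.ndarray:
    """Estimate the circular field of view from image luminance.

    Pixels with luminance above ``threshold`` after morphological closing
    (disk of ``closing_radius``). STARE ships no FOV masks, so this fills
    the gap when none is given.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    rough = gray > threshold
    selem = disk(closing_radius)
    closed = ndimage.binary_closing(rough, structure=selem)
    # closing cannot recover pixels eroded at the raster border; keep rough ones
    return closed | rough
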