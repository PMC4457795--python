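"""Local gray-voting contrast enhancement and multiplicative fusion.

For each pixel, the m x m window around it votes: with
``Comparison = Center - k``, every neighbor (the m^2 - 1 window pixels
other than the center) with value >= Comparison counts toward ``Num1``,
the rest toward ``Num2``, and the outcome is

    P_vote = Num1 * L + Num2 * N,
    L = M_max / (m^2 - 1),   N = -M_min / (m^2 - 1)

with ``M_max`` / ``M_min`` the maximum and minimum normalized gray value
inside the window. The gray transition scale ``k`` trades small-vessel
sensitivity against noise: raising k demands a larger local gray drop
before a neighbor is counted as brighter. A second parameterization
(``l_mode="max_max"``, used by the complement pass with negative k)
takes ``N = -M_max / (m^2 - 1)`` so both vote weights derive from the
window maximum.

``k`` here is in normalized [0, 1] units; the conventional settings on
the 0-255 gray scale (k = 3 for the main pass, k = -5 for the
complement pass) correspond to ``k = 3/255`` and ``k = -5/255``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["GrayVoteParams", "gray_vote", "fuse", "binarize", "rescale01",
           "otsu_threshold"]

K_MAIN = 3.0 / 255.0
K_COMPLEMENT = -5.0 / 255.0


@dataclass
class GrayVoteParams:
    m: int = 11
    k: float = K_MAIN
    l_mode: str = "max_min"  # "max_min" (main pass) or "max_max" (complement pass)

    def __post_init__(self) -> None:
        if self.m % 2 == 0 or self.m < 3:
            raise ValueError("window side m must be odd and >= 3")
        if self.l_mode not in ("max_min", "max_max"):
            raise ValueError("l_mode must be 'max_min' or 'max_max'")


def gray_vote(
    img: np.ndarray,
    params: GrayVoteParams | None = None,
    fov: np.ndarray | None = None,
    chunk_rows: int = 64,
) -> np.ndarray:
    """Gray-voting outcome P_vote for every pixel.

    The raster is reflect-padded so border windows are full. When a FOV
    mask is given, out-of-FOV pixels are excluded from the neighbor
    counts and from M_max / M_min, the weights are renormalized by the
    actual neighbor count, and out-of-FOV output pixels are set to 0.
    Windows are processed in row chunks to bound memory.
    """
    params = params or GrayVoteParams()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    m, k = params.m, params.k
    if m > min(img.shape):
        raise ValueError(f"window m={m} does not fit image of shape {img.shape}")
    half = m // 2

    if fov is None:
        valid = np.ones(img.shape, dtype=bool)
    else:
        valid = np.asarray(fov, dtype=bool)
        if valid.shape != img.shape:
            raise ValueError("fov shape must match image shape")

    pad_img = np.pad(img, half, mode="symmetric")
    pad_valid = np.pad(valid, half, mode="symmetric")
    win_img = sliding_window_view(pad_img, (m, m))
    win_valid = sliding_window_view(pad_valid, (m, m))

    out = np.zeros(img.shape, dtype=np.float64)
    h = img.shape[0]
    for r0 in range(0, h, chunk_rows):
        r1 = min(h, r0 + chunk_rows)
        wi = win_img[r0:r1]          # (rows, W, m, m) view
        wv = win_valid[r0:r1]
        center = img[r0:r1]
        comparison = center - k

        n_window = wv.sum(axis=(2, 3))
        n_neighbors = n_window - 1   # center always counts itself out
        ge = (wi >= comparison[:, :, None, None]) & wv
        num1 = ge.sum(axis=(2, 3)) - (center >= comparison)  # drop the center
        num2 = n_neighbors - num1

        big = np.where(wv, wi, -np.inf).max(axis=(2, 3))
        small = np.where(wv, wi, np.inf).min(axis=(2, 3))
        with np.errstate(divide="ignore", invalid="ignore"):
            ell = big / n_neighbors
            if params.l_mode == "max_min":
                enn = -small / n_neighbors
            else:
                enn = -big / n_neighbors
            vote = num1 * ell + num2 * enn
        vote[n_neighbors <= 0] = 0.0
        vote[~valid[r0:r1]] = 0.0
        out[r0:r1] = vote
    return out


def fuse(gabor: np.ndarray, vote: np.ndarray) -> np.ndarray:
    """Multiplicative fusion I_gv = I_Gabor * (1 - I_vessel).

    Both inputs are expected rescaled to [0, 1]; the product keeps the
    main structure from the Gabor response and the small-vessel detail
    carried by the gray-voting image.
    """
    gabor = np.asarray(gabor, dtype=np.float64)
    vote = np.asarray(vote, dtype=np.float64)
    if gabor.shape != vote.shape:
        raise ValueError(f"shape mismatch: {gabor.shape} vs {vote.shape}")
    return gabor * (1.0 - vote)


def rescale01(img: np.ndarray, fov: np.ndarray | None = None) -> np.ndarray:
    """Min-max rescale to [0, 1] over in-FOV pixels; out-of-FOV set to 0."""
    img = np.asarray(img, dtype=np.float64)
    sel = img if fov is None else img[fov]
    if sel.size == 0:
        return np.zeros_like(img)
    lo, hi = sel.min(), sel.max()
    if hi <= lo:
        out = np.zeros_like(img)
    else:
        out = (img - lo) / (hi - lo)
    if fov is not None:
        out = np.where(fov, out, 0.0)
    return np.clip(out, 0.0, 1.0)


def otsu_threshold(values: np.ndarray) -> float:
    """Exact Otsu threshold: exhaustive search over all distinct splits.

    Maximizes the between-class variance w0*w1*(mu0 - mu1)^2 over every
    split between consecutive sorted values (no histogram binning, so
    the result is invariant to the sample's value range). Returns the
    midpoint of the optimal gap; pixels strictly above it are foreground.
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = v.size
    if n < 2 or v[0] == v[-1]:
        raise ValueError("need at least two distinct values")
    csum = np.cumsum(v)
    total = csum[-1]
    n0 = np.arange(1, n)                  # size of the lower class per split
    mu0 = csum[:-1] / n0
    mu1 = (total - csum[:-1]) / (n - n0)
    between = n0 * (n - n0) * (mu0 - mu1) ** 2
    between[v[1:] == v[:-1]] = -np.inf    # splits inside a tie are not valid
    best = int(np.argmax(between))
    return 0.5 * (v[best] + v[best + 1])


def binarize(
    img: np.ndarray, method: str = "otsu", fov: np.ndarray | None = None
) -> np.ndarray:
    """Threshold a real image to a boolean mask.

    ``otsu`` computes the exact Otsu threshold over in-FOV pixels and
    keeps pixels above it; ``zero`` keeps strictly positive pixels. A
    constant image yields an all-false mask with a warning.
    """
    img = np.asarray(img, dtype=np.float64)
    if method == "zero":
        mask = img > 0
    elif method == "otsu":
        sel = img if fov is None else img[fov]
        if sel.size == 0 or np.ptp(sel) == 0:
            warnings.warn("degenerate constant image; returning empty mask")
            return np.zeros(img.shape, dtype=bool)
        thresh = otsu_threshold(sel)
        mask = img > thresh
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    if fov is not None:
        mask = mask & np.asarray(fov, dtype=bool)
    return mask
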