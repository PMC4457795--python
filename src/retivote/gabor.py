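"""Orientation-maximum 2D Gabor wavelet filtering.

The analyzing wavelet is an anisotropic complex Gabor function

    psi(x) = exp(j k0 . x) * exp(-|A x|^2 / 2),    A = diag(eps^-1/2, 1)

with anisotropy ``eps >= 1`` stretching the Gaussian envelope along the
first axis and a plane-wave modulation ``k0`` (default (0, 3)) across
the second, so the filter is an elongated oriented ridge detector. The
transform at scale ``a`` and rotation ``theta`` is the cross-correlation
of the image with the dilated, rotated wavelet, computed densely over
all translations by FFT. Per pixel, the maximum modulus over a discrete
orientation grid (0..170 degrees in 10-degree steps by default) yields
the vessel-structure response ``I_Gabor``.

The wavelet's normalizing constant only scales the response globally; it
is folded into the final rescaling of the orientation maximum to [0, 1],
since downstream fusion multiplies normalized images. Angles follow the
image convention: theta is measured from the +column axis toward the
+row axis, and at theta the elongated envelope axis lies along a line at
that angle, so a straight ridge drawn at angle theta responds maximally
near theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GaborParams", "gabor_kernel", "gabor_transform", "orientation_max"]


@dataclass
class GaborParams:
    a: float = 3.0
    epsilon: float = 4.0
    k0: tuple[float, float] = (0.0, 3.0)
    theta_step_deg: float = 10.0
    theta_max_deg: float = 170.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale a must be positive")
        if self.epsilon < 1:
            raise ValueError("anisotropy epsilon must be >= 1")
        if not 0 < self.theta_step_deg <= self.theta_max_deg < 180:
            raise ValueError("need 0 < theta_step_deg <= theta_max_deg < 180")

    def thetas(self) -> np.ndarray:
        """The orientation grid in degrees."""
        return np.arange(0.0, self.theta_max_deg + 0.5 * self.theta_step_deg,
                         self.theta_step_deg)

    def kernel_halfwidth(self) -> int:
        # envelope decays below 1e-5 at the border: |x| > sigma*sqrt(2 ln 1e5)
        reach = np.sqrt(2.0 * np.log(1e5))  # ~4.80
        return int(np.ceil(self.a * max(np.sqrt(self.epsilon), 1.0) * reach))


def gabor_kernel(params: GaborParams, theta_deg: float) -> np.ndarray:
    """Sample the rotated, dilated wavelet psi(a^-1 r_-theta u) on a grid.

    ``u = (row, col)`` offsets from the kernel center; the returned array
    has odd side ``2*halfwidth + 1`` and value exactly 1 at its center.
    """
    half = params.kernel_halfwidth()
    rows = np.arange(-half, half + 1, dtype=np.float64)
    cols = np.arange(-half, half + 1, dtype=np.float64)
    # spatial axes: x along +col, y along +row (image convention)
    y = rows[:, None]
    x = cols[None, :]
    t = np.deg2rad(theta_deg)
    # rotate by -theta, then dilate by a
    x1 = (np.cos(t) * x + np.sin(t) * y) / params.a
    x2 = (-np.sin(t) * x + np.cos(t) * y) / params.a
    k1, k2 = params.k0
    phase = k1 * x1 + k2 * x2
    envelope = np.exp(-0.5 * (x1**2 / params.epsilon + x2**2))
    return np.exp(1j * phase) * envelope


def gabor_transform(
    img: np.ndarray, params: GaborParams, theta_deg: float
) -> np.ndarray:
    """Dense complex Gabor response at one orientation, via the FFT.

    The image is reflect-padded by the kernel half-width to suppress
    wrap-around, then correlated with the conjugate wavelet in the
    frequency domain. Output shape equals input shape.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D gray image")
    kernel = gabor_kernel(params, theta_deg)
    half = kernel.shape[0] // 2
    if kernel.shape[0] > min(img.shape):
        raise ValueError(
            f"kernel side {kernel.shape[0]} exceeds image size {img.shape}; "
            "use a smaller scale a"
        )
    padded = np.pad(img, half, mode="symmetric")
    kfull = np.zeros(padded.shape, dtype=np.complex128)
    kfull[: kernel.shape[0], : kernel.shape[1]] = kernel
    kfull = np.roll(kfull, (-half, -half), axis=(0, 1))  # center kernel at (0, 0)
    # cross-correlation: IFFT( FFT(f) * conj(FFT(k)) )
    resp = np.fft.ifft2(np.fft.fft2(padded) * np.conj(np.fft.fft2(kfull)))
    return resp[half : half + img.shape[0], half : half + img.shape[1]]


def orientation_max(
    img: np.ndarray,
    params: GaborParams | None = None,
    fov: np.ndarray | None = None,
    rescale: bool = True,
    return_argmax: bool = False,
):
    """Per-pixel maximum Gabor modulus over the orientation grid (I_Gabor).

    When ``rescale`` is set the result is divided by its in-FOV maximum
    so it lies in [0, 1], the convention required by the multiplicative
    fusion with the gray-voting image. ``return_argmax`` additionally
    returns the winning orientation (degrees) per pixel.
    """
    params = params or GaborParams()
    img = np.asarray(img, dtype=np.float64)
    best = np.zeros_like(img)
    arg = np.zeros_like(img)
    for theta in params.thetas():
        mod = np.abs(gabor_transform(img, params, theta))
        better = mod > best
        best[better] = mod[better]
        arg[better] = theta
    if fov is not None:
        best = np.where(fov, best, 0.0)
    if rescale:
        peak = best.max() if fov is None else (best[fov].max() if fov.any() else 0.0)
        if peak > 0:
            best = best / peak
    if return_argmax:
        return best, arg
    return best
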