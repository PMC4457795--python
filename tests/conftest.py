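"""Shared fixtures and independent brute-force oracles."""

import numpy as np
import pytest

from retivote.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 256x256 phantom used by stage-level tests (fast to segment)."""
    spec = PhantomSpec(
        height=256, width=256, n_trees=4, main_width=4.0,
        vessel_contrast=0.3, noise_sd=0.005, rng_seed=11,
        disc_radius=20.0, fovea_radius=25.0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-noise, high-contrast full-size phantom (acceptance conditions)."""
    spec = PhantomSpec(rng_seed=0, noise_sd=0.0, vessel_contrast=0.35)
    return generate_phantom(spec)


def gray_vote_oracle(img, m, k, l_mode="max_min", fov=None):
    """Brute-force gray-voting: enumerate every neighbor of every window.

    Direct transcription of the voting rule, accumulating Num1/Num2 and
    the window extrema one offset at a time — structurally independent
    of the production sliding-window implementation.
    """
    img = np.asarray(img, dtype=np.float64)
    half = m // 2
    pad = np.pad(img, half, mode="symmetric")
    valid = np.ones(img.shape, bool) if fov is None else np.asarray(fov, bool)
    pv = np.pad(valid, half, mode="symmetric")
    h, w = img.shape
    comparison = img - k
    num1 = np.zeros(img.shape)
    n_nb = np.zeros(img.shape)
    mmax = np.full(img.shape, -np.inf)
    mmin = np.full(img.shape, np.inf)
    for du in range(m):
        for dv in range(m):
            nb = pad[du : du + h, dv : dv + w]
            ok = pv[du : du + h, dv : dv + w]
            mmax = np.where(ok & (nb > mmax), nb, mmax)
            mmin = np.where(ok & (nb < mmin), nb, mmin)
            if du == half and dv == half:
                continue  # the center does not vote
            num1 += ok & (nb >= comparison)
            n_nb += ok
    num2 = n_nb - num1
    with np.errstate(divide="ignore", invalid="ignore"):
        ell = mmax / n_nb
        enn = (-mmin if l_mode == "max_min" else -mmax) / n_nb
        out = num1 * ell + num2 * enn
    out[(n_nb <= 0) | ~valid] = 0.0
    return out


def gray_vote_oracle_pixelwise(img, m, k, l_mode="max_min"):
    """Even more literal oracle: an explicit per-pixel window loop."""
    img = np.asarray(img, dtype=np.float64)
    half = m // 2
    pad = np.pad(img, half, mode="symmetric")
    out = np.zeros_like(img)
    n_nb = m * m - 1
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            win = pad[i : i + m, j : j + m]
            center = img[i, j]
            comparison = center - k
            num1 = int((win >= comparison).sum()) - int(center >= comparison)
            num2 = n_nb - num1
            ell = win.max() / n_nb
            enn = (-win.min() if l_mode == "max_min" else -win.max()) / n_nb
            out[i, j] = num1 * ell + num2 * enn
    return out


def flood_fill_components(mask, connectivity=8):
    """BFS flood-fill labeling oracle; labels in raster discovery order."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    if connectivity == 8:
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                   (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offsets = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    current = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                queue = [(i, j)]
                labels[i, j] = current
                while queue:
                    r, c = queue.pop()
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                and labels[rr, cc] == 0):
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels
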