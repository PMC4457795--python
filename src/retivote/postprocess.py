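"""Fragment complementation and squareness-based elimination.

The GMM vessel layer (the *marker* image) captures the main vessel tree
but breaks small vessels into tiny fragments. A second, more permissive
gray-voting pass yields a binary *complement* image rich in small-vessel
detail. Complementation adopts complement fragments into the marker:
every marker component of at most ``T_seed`` pixels is treated as a
broken-vessel seed; the complement component underneath its first pixel
is copied into the output wholesale, provided it has at most
``T_fragment`` pixels. Marker pixels are never removed.

Elimination then discards residual noise blobs by their squareness rate

    S_Rcs = 100 * F_Scs / (1 + mx^2)

where ``F_Scs`` is the component pixel count and ``mx`` is the larger of
the component's maximum coordinates along the two axes (``mx_mode=
"coordinate"``, the published form) or of its bounding-box extents
(``mx_mode="extent"``). A component is removed iff ``F_Scs < size_cut``
and ``S_Rcs > squareness_cut``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label

__all__ = [
    "LabeledComponents",
    "ComplementParams",
    "EliminationParams",
    "label_components",
    "complement_vessels",
    "squareness_rate",
    "eliminate_fragments",
]


@dataclass
class LabeledComponents:
    """Connected components: label raster, pixel counts, bounding boxes.

    ``labels`` uses 0 for background and 1..num for components in
    deterministic raster-scan discovery order. ``bboxes[i]`` is
    (row_min, row_max, col_min, col_max), inclusive, for label i+1.
    """

    labels: np.ndarray
    counts: np.ndarray   # counts[i] = pixel count of label i+1
    bboxes: np.ndarray   # (num, 4) int

    @property
    def num(self) -> int:
        return self.counts.size


@dataclass
class ComplementParams:
    t_seed: int = 30
    t_fragment: int = 100
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.t_seed < 1 or self.t_fragment < self.t_seed:
            raise ValueError("need t_fragment >= t_seed >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class EliminationParams:
    size_cut: int = 14000
    squareness_cut: float = 0.2
    connectivity: int = 8
    mx_mode: str = "coordinate"  # or "extent"

    def __post_init__(self) -> None:
        if self.size_cut <= 0 or self.squareness_cut <= 0:
            raise ValueError("cuts must be positive")
        if self.mx_mode not in ("coordinate", "extent"):
            raise ValueError("mx_mode must be 'coordinate' or 'extent'")


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledComponents:
    """8- or 4-connected component labeling of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    labels = sk_label(mask, connectivity=2 if connectivity == 8 else 1)
    num = labels.max()
    if num == 0:
        return LabeledComponents(labels, np.zeros(0, int), np.zeros((0, 4), int))
    counts = np.bincount(labels.ravel())[1:]
    slices = ndimage.find_objects(labels)
    bboxes = np.array(
        [
            (sl[0].start, sl[0].stop - 1, sl[1].start, sl[1].stop - 1)
            for sl in slices
        ],
        dtype=int,
    )
    return LabeledComponents(labels, counts, bboxes)


def complement_vessels(
    marker: np.ndarray,
    complement: np.ndarray,
    params: ComplementParams | None = None,
) -> np.ndarray:
    """Adopt small complement fragments under broken marker seeds.

    For every marker component with pixel count in [1, t_seed], the
    complement label at the component's first pixel (row-major scan
    order) is looked up; when that label is foreground and its component
    has at most t_fragment pixels, the whole complement component is set
    in the output. The output always contains the full marker.
    """
    params = params or ComplementParams()
    marker = np.asarray(marker, dtype=bool)
    complement = np.asarray(complement, dtype=bool)
    if marker.shape != complement.shape:
        raise ValueError(f"shape mismatch: {marker.shape} vs {complement.shape}")

    comp_lab = label_components(complement, params.connectivity)
    mark_lab = label_components(marker, params.connectivity)
    out = marker.copy()
    if mark_lab.num == 0:
        return out

    # first pixel of each marker component in raster order
    flat = mark_lab.labels.ravel()
    first_flat = np.full(mark_lab.num + 1, -1, dtype=np.int64)
    seen = flat != 0
    idx = np.flatnonzero(seen)
    # reversed so the earliest raster index wins
    first_flat[flat[idx[::-1]]] = idx[::-1]

    adopted = np.zeros(comp_lab.num + 1, dtype=bool)
    for lab in range(1, mark_lab.num + 1):
        if not 1 <= mark_lab.counts[lab - 1] <= params.t_seed:
            continue
        t = comp_lab.labels.ravel()[first_flat[lab]]
        if t > 0 and comp_lab.counts[t - 1] <= params.t_fragment:
            adopted[t] = True
    if adopted.any():
        out |= adopted[comp_lab.labels]
    return out


def squareness_rate(count: int, mx: float) -> float:
    """S_Rcs = 100 * F_Scs / (1 + mx^2); ~100 for compact squares, small
    for sparse or far-reaching components."""
    if count < 1 or mx < 1:
        raise ValueError("need count >= 1 and mx >= 1")
    return 100.0 * count / (1.0 + mx * mx)


def _component_mx(bbox: np.ndarray, mode: str) -> float:
    r0, r1, c0, c1 = bbox
    if mode == "extent":
        return float(max(r1 - r0 + 1, c1 - c0 + 1))
    # maximum coordinate along either axis, 1-based as in the published rule
    return float(max(r1 + 1, c1 + 1))


def eliminate_fragments(
    mask: np.ndarray, params: EliminationParams | None = None
) -> np.ndarray:
    """Remove components that are small and too square to be vessels.

    A component is deleted iff its pixel count is below ``size_cut`` AND
    its squareness rate exceeds ``squareness_cut``; everything else is
    kept verbatim.
    """
    params = params or EliminationParams()
    lab = label_components(np.asarray(mask, dtype=bool), params.connectivity)
    if lab.num == 0:
        return np.zeros(np.asarray(mask).shape, dtype=bool)
    keep = np.ones(lab.num + 1, dtype=bool)
    keep[0] = False
    for i in range(lab.num):
        count = int(lab.counts[i])
        mx = _component_mx(lab.bboxes[i], params.mx_mode)
        if count < params.size_cut and squareness_rate(count, mx) > params.squareness_cut:
            keep[i + 1] = False
    return keep[lab.labels]
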