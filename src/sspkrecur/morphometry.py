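"""Tumor size metrics and ROI bookkeeping.

Longest diameter follows the RECIST axial convention: per axial slice, the
largest center-to-center distance between in-plane mask voxels, plus one
in-plane voxel size so a single voxel reports its physical extent rather
than zero. Percent changes are stored as fractions (a halving is -0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

__all__ = ["RoiMask", "longest_diameter", "percent_change", "transfer_roi_v3_to_v4"]

VISITS = ("V1", "V2", "V3", "V4")


@dataclass
class RoiMask:
    """Boolean tumor mask on a regular voxel grid.

    `spacing` is (in-plane row mm, in-plane column mm, slice thickness mm);
    axis 2 indexes axial slices.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.4)
    visit: str = "V1"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be a 3-D voxel grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.visit not in VISITS:
            raise ValueError(f"visit must be one of {VISITS}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _max_pairwise(points: np.ndarray) -> float:
    """Exact in-plane diameter of a point set (hull shortcut for big sets)."""
    if len(points) == 1:
        return 0.0
    if len(points) > 400:
        hull = ConvexHull(points, qhull_options="QJ")
        points = points[hull.vertices]
    return float(pdist(points).max())


def longest_diameter(mask: RoiMask) -> float:
    """RECIST longest diameter (mm): max over axial slices of the in-slice
    voxel-center diameter, plus one in-plane voxel size."""
    if not mask.data.any():
        raise ValueError("empty ROI mask has no longest diameter")
    dr, dc, _ = mask.spacing
    best = 0.0
    for k in range(mask.data.shape[2]):
        sl = mask.data[:, :, k]
        if not sl.any():
            continue
        pts = np.argwhere(sl).astype(float) * np.array([dr, dc])
        best = max(best, _max_pairwise(pts))
    return best + max(dr, dc)


def percent_change(v1_value: float, v4_value: float) -> float:
    """Change of a metric at the final visit relative to baseline, as a
    fraction: (v4 - v1)/v1. Undefined (NaN) when the baseline is not positive."""
    if v1_value is None or not np.isfinite(v1_value) or v1_value <= 0:
        return float("nan")
    if v4_value is None or not np.isfinite(v4_value):
        return float("nan")
    return (v4_value - v1_value) / v1_value


def transfer_roi_v3_to_v4(mask_v3: RoiMask, v4_shape, center_slice_index: int,
                          v3_center_slice: int | None = None,
                          v4_spacing: tuple | None = None) -> RoiMask:
    """Copy three consecutive central-slice ROIs from a V3 mask into a V4 grid.

    Used when the final-visit study shows no contrast-enhancing tumor: three
    consecutive slices through the central portion of the mid-treatment tumor
    are pasted at `center_slice_index` (0-based) of the final-visit grid.
    """
    if not mask_v3.data.any():
        raise ValueError("V3 mask is empty; nothing to transfer")
    if tuple(v4_shape[:2]) != mask_v3.data.shape[:2]:
        raise ValueError("in-plane grids of V3 and V4 must match")
    if v3_center_slice is None:
        occupied = np.flatnonzero(mask_v3.data.any(axis=(0, 1)))
        weights = mask_v3.data.sum(axis=(0, 1))[occupied]
        v3_center_slice = int(round(float(np.average(occupied, weights=weights))))
    src = [v3_center_slice - 1, v3_center_slice, v3_center_slice + 1]
    if src[0] < 0 or src[-1] >= mask_v3.data.shape[2]:
        raise ValueError("central V3 slices out of bounds")
    dst = [center_slice_index - 1, center_slice_index, center_slice_index + 1]
    if dst[0] < 0 or dst[-1] >= v4_shape[2]:
        raise ValueError("target V4 slices out of bounds")
    out = np.zeros(tuple(v4_shape), dtype=bool)
    for s, d in zip(src, dst):
        out[:, :, d] = mask_v3.data[:, :, s]
    if not out.any():
        raise ValueError("transferred central slices contain no tumor voxels")
    return RoiMask(out, v4_spacing or mask_v3.spacing, visit="V4")
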