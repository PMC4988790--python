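"""Distance transforms, adaptive patch sizing and the inward filling order.

The patch side ``w`` adapts to lesion thickness: it is one more than the
largest Euclidean distance from any lesion voxel to the closest healthy
voxel, so that even the deepest voxel's patch can reach observed tissue.
The search window side is ``4w`` (both rounded up to odd so they can be
centred on a voxel).  Lesion voxels are processed boundary-first —
concentrically inwards — so freshly synthesised voxels inform deeper ones.

Distances are computed in isotropic index space (voxel units); anisotropic
voxel sizes are deliberately ignored for sizing, which only needs an upper
bound on lesion thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PatchGeometry",
    "nonlesion_distance_map",
    "adaptive_patch_width",
    "search_window_side",
    "processing_schedule",
    "patch_offsets",
]


def nonlesion_distance_map(excluded: np.ndarray) -> np.ndarray:
    """Euclidean distance (voxels) from each excluded voxel to the nearest
    non-excluded voxel; exactly 0 outside the set.

    ``excluded`` is typically the excluded-source set (lesions plus
    prior-invalid tissue), so the returned map is the distance to the closest
    voxel that may serve as a synthesis source.
    """
    excluded = np.asarray(excluded, dtype=bool)
    if excluded.all():
        raise ValueError("excluded set covers the entire image: nothing to copy from")
    return ndimage.distance_transform_edt(excluded)


def _odd_at_least(value: float, minimum: int = 3) -> int:
    side = int(np.ceil(value))
    if side % 2 == 0:
        side += 1
    return max(side, minimum)


def adaptive_patch_width(dist_map: np.ndarray, spatial_fill_set: np.ndarray) -> int:
    """Global adaptive patch side: max over lesion voxels of (distance to the
    nearest usable voxel) + 1, rounded up to the nearest odd integer >= 3."""
    fill = np.asarray(spatial_fill_set, dtype=bool)
    if not fill.any():
        raise ValueError("empty fill set: no lesion voxels to size the patch for")
    w_raw = float(np.max(dist_map[fill])) + 1.0
    return _odd_at_least(w_raw)


def search_window_side(side: int, multiplier: int = 4) -> int:
    """Search window side W = multiplier * w, rounded up to odd for centring."""
    if side < 3 or side % 2 == 0:
        raise ValueError("patch side must be odd and >= 3")
    w = multiplier * side
    return w + 1 if w % 2 == 0 else w


def processing_schedule(spatial_fill_set: np.ndarray,
                        excluded: np.ndarray | None = None) -> np.ndarray:
    """Order fill-set voxels boundary-first (increasing distance to usable
    tissue), ties broken lexicographically by (z, y, x) index.

    Returns an (N, 3) int array of (x, y, z) voxel indices.
    """
    fill = np.asarray(spatial_fill_set, dtype=bool)
    if not fill.any():
        raise ValueError("empty fill set")
    if excluded is None:
        excluded = fill
    dist = nonlesion_distance_map(np.asarray(excluded, dtype=bool))
    xs, ys, zs = np.nonzero(fill)
    order = np.lexsort((xs, ys, zs, dist[xs, ys, zs]))
    return np.stack([xs[order], ys[order], zs[order]], axis=1)


def patch_offsets(side: int) -> np.ndarray:
    """The side**3 spatial offsets of a cubic patch, relative to its centre.

    Ordered lexicographically by (z, y, x) offset for determinism.
    """
    if side < 3 or side % 2 == 0:
        raise ValueError("patch side must be odd and >= 3")
    h = side // 2
    zz, yy, xx = np.meshgrid(*([np.arange(-h, h + 1)] * 3), indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


@dataclass
class PatchGeometry:
    """A cubic patch footprint centred at a voxel, plus its search window."""

    centre: tuple[int, int, int]
    side: int
    window_side: int
    offsets: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.side < 3 or self.side % 2 == 0:
            raise ValueError("patch side must be odd and >= 3")
        if self.window_side < self.side:
            raise ValueError("window side must be >= patch side")
        self.offsets = patch_offsets(self.side)

    def window_bounds(self, shape) -> tuple[slice, slice, slice]:
        """The search window around the centre, clipped to the image bounds."""
        h = self.window_side // 2
        return tuple(
            slice(max(0, c - h), min(s, c + h + 1))
            for c, s in zip(self.centre, shape)
        )
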