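"""Joint multi-time-point filling in a log-Euclidean mean space.

Given pairwise affine transforms T_{i,j} mapping image i into image j's
frame (registration itself is an external step; matrices arrive as
plain-text files), the unbiased average space for image i is

    T_{h,i} = exp( (1/N) Σ_j log T_{i,j} ),

the matrix exponential of the arithmetic mean of principal matrix
logarithms (the log of T_{i,i} = I contributes zero).  All channels and
masks are resampled into that space (trilinear for intensities, nearest
neighbour + 0.5 binarisation for masks), stacked into one 5D volume, filled
jointly — so a single best source q̂ feeds every time-point and modality at
each voxel — and optionally mapped back to native space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import expm, logm

from .inpaint_core import FillParams, apply_buffing, inpaint_5d, make_buff_kernel
from .io_volumes import assemble_5d

__all__ = [
    "AffineTransform",
    "mean_space_transform",
    "pairwise_from_absolute",
    "resample_channels",
    "longitudinal_inpaint",
]

logger = logging.getLogger(__name__)


@dataclass
class AffineTransform:
    """Homogeneous 4x4 spatial transform from one image's frame to another's."""

    matrix: np.ndarray
    from_index: int = 0
    to_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-8):
            raise ValueError("last row of a homogeneous affine must be 0 0 0 1")
        if np.linalg.det(self.matrix[:3, :3]) <= 0:
            raise ValueError("no real logarithm: transform has non-positive determinant")


def _real_logm(matrix: np.ndarray) -> np.ndarray:
    if np.linalg.det(np.asarray(matrix)[:3, :3]) <= 0:
        raise ValueError("no real logarithm: transform has non-positive determinant")
    log = logm(matrix)
    if np.max(np.abs(np.imag(log))) > 1e-8:
        raise ValueError("no real logarithm for this transform")
    return np.real(log)


def mean_space_transform(pairwise, i: int, n_images: int) -> np.ndarray:
    """Log-Euclidean mean transform T_{h,i} from image i to the average space.

    ``pairwise`` maps (from, to) index pairs to 4x4 matrices (dict or nested
    sequence); T_{i,i} is taken as identity if absent.
    """
    if n_images < 1:
        raise ValueError("need at least one image")
    acc = np.zeros((4, 4))
    for j in range(n_images):
        if j == i:
            continue  # log(identity) = 0
        try:
            mat = pairwise[i, j]
        except (KeyError, TypeError, IndexError):
            mat = pairwise[i][j]
        mat = mat.matrix if isinstance(mat, AffineTransform) else np.asarray(mat, float)
        acc += _real_logm(mat)
    return expm(acc / n_images)


def pairwise_from_absolute(absolute: list[np.ndarray]) -> dict:
    """Consistent pairwise set T_{i,j} = A_j^-1 A_i from per-image transforms
    A_i (each mapping image i into a common reference frame)."""
    inv = [np.linalg.inv(a) for a in absolute]
    return {(i, j): inv[j] @ absolute[i]
            for i in range(len(absolute)) for j in range(len(absolute))}


def _warp(volume: np.ndarray, to_avg: np.ndarray, order: int) -> np.ndarray:
    """Resample onto the average grid: out(x) = in(T_{h}^-1 x)."""
    inv = np.linalg.inv(to_avg)
    return ndimage.affine_transform(volume, inv[:3, :3], offset=inv[:3, 3],
                                    order=order, mode="constant", cval=0.0)


def resample_channels(images, masks, transforms, priors=None):
    """Resample per-time-point images/masks into the average space.

    ``transforms[i]`` is T_{h,i} (native i → average, voxel coordinates).
    Images use trilinear interpolation; masks nearest-neighbour and are then
    binarised at > 0.5.  Regions with no source data are zero-filled (with a
    warning when a volume leaves the field of view entirely).
    """
    out_images, out_masks, out_priors = [], [], []
    for i, (img, msk) in enumerate(zip(images, masks)):
        t = transforms[i]
        t = t.matrix if isinstance(t, AffineTransform) else np.asarray(t, float)
        w_img = _warp(np.asarray(img, float), t, order=1)
        w_msk = _warp(np.asarray(msk, float), t, order=0) > 0.5
        if np.asarray(img).any() and not w_img.any():
            logger.warning("time-point %d has no overlap with the average-space "
                           "field of view; zero-filled", i)
        out_images.append(w_img)
        out_masks.append(w_msk)
        if priors is not None:
            out_priors.append(_warp(np.asarray(priors[i], float), t, order=0) > 0.5)
    return out_images, out_masks, (out_priors if priors is not None else None)


def longitudinal_inpaint(images, masks, pairwise=None, priors=None,
                         params: FillParams | None = None, native: bool = False,
                         affine: np.ndarray | None = None):
    """Fill all time-points of one subject jointly.

    Parameters
    ----------
    images, masks : per-time-point 3D arrays (one modality).
    pairwise : dict (i, j) → 4x4 voxel-space transforms, or None for
        identity alignment (already-registered inputs).
    priors : per-time-point healthy-tissue masks, optional; their
        intersection in the average space defines the prior for the joint fill.
    native : if True, map each filled time-point back to its own frame;
        default is to return the average-space volumes.

    Returns ``(filled_timepoints, fill_log, mean_transforms)``.
    """
    params = params or FillParams()
    n = len(images)
    if n != len(masks):
        raise ValueError("need one mask per time-point")
    affine = np.eye(4) if affine is None else affine

    if pairwise is None:
        mean_transforms = [np.eye(4) for _ in range(n)]
    else:
        mean_transforms = [mean_space_transform(pairwise, i, n) for i in range(n)]

    if n == 1:
        imgs, msks, prs = [np.asarray(images[0], float)], [np.asarray(masks[0], bool)], priors
    else:
        imgs, msks, prs = resample_channels(images, masks, mean_transforms, priors)

    prior = None
    if prs:
        prior = np.logical_and.reduce(prs)

    volume, maskset = assemble_5d(
        [(0, t, imgs[t]) for t in range(len(imgs))],
        [(0, t, msks[t]) for t in range(len(msks))],
        prior=prior, affine=affine)
    filled, log = inpaint_5d(volume, maskset, params)
    buffed = apply_buffing(filled, maskset, make_buff_kernel(params.kernel_k))

    out = [buffed.data[:, :, :, 0, t] for t in range(buffed.n_timepoints)]
    if native and pairwise is not None:
        back = []
        for t_idx, vol in enumerate(out):
            m = mean_transforms[t_idx]
            # native(x) = avg(T_{h,i} x)
            back.append(ndimage.affine_transform(vol, m[:3, :3], offset=m[:3, 3],
                                                 order=1, mode="constant", cval=0.0))
        out = back
    return out, log, mean_transforms
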