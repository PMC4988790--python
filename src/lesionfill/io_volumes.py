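"""NIfTI and plain-text affine I/O, and assembly of the 5D image stack.

The central container is :class:`Volume5D`: a single intensity array indexed
``(x, y, z, n, t)`` holding ``n`` modalities over ``t`` time-points on one
spatial grid.  Channels are ordered modality-major — flattened channel index
``c = n * n_timepoints + t`` — and that layout is recorded in the NIfTI
header description on write.

Masks travel in a :class:`ChannelMaskSet`: per-channel binary lesion masks
plus an optional "prior" mask of voxels considered healthy and usable as
synthesis sources.  Two spatial sets are derived from them:

* ``spatial_fill_set`` — the union over all channels of the lesion masks;
  these voxels will be synthesised.
* ``excluded_source_set`` — the fill set plus everything outside the prior;
  these voxels are never used as patch-search centres.

All voxel coordinates in this package are 0-based indices; world coordinates
exist only through ``voxel_to_world``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume5D",
    "ChannelMaskSet",
    "load_volume",
    "save_volume",
    "load_affine_text",
    "save_affine_text",
    "assemble_5d",
    "AFFINE_TOL",
]

#: tolerance on affine entries when checking that two volumes share a grid
#: (absorbs float32 header round-off)
AFFINE_TOL = 1e-4


@dataclass
class Volume5D:
    """Multi-modal, multi-time-point image stack on a single spatial grid."""

    data: np.ndarray  # (X, Y, Z, n, t), float
    voxel_to_world: np.ndarray  # 4x4
    n_modalities: int = field(init=False)
    n_timepoints: int = field(init=False)

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError(f"Volume5D data must be 5-dimensional, got {self.data.ndim}D")
        self.n_modalities = self.data.shape[3]
        self.n_timepoints = self.data.shape[4]
        self.voxel_to_world = np.asarray(self.voxel_to_world, dtype=float)
        if self.voxel_to_world.shape != (4, 4):
            raise ValueError("voxel_to_world must be 4x4")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.n_modalities * self.n_timepoints

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine's column norms."""
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)

    def channels(self) -> np.ndarray:
        """View the stack as (C, X, Y, Z), modality-major (c = n * t_count + t)."""
        x, y, z, n, t = self.data.shape
        return np.moveaxis(self.data.reshape(x, y, z, n * t), -1, 0)

    @classmethod
    def from_channels(cls, channels: np.ndarray, n_modalities: int, n_timepoints: int,
                      voxel_to_world: np.ndarray) -> "Volume5D":
        """Inverse of :meth:`channels`."""
        c, x, y, z = channels.shape
        if c != n_modalities * n_timepoints:
            raise ValueError("channel count does not match n_modalities * n_timepoints")
        data = np.moveaxis(channels, 0, -1).reshape(x, y, z, n_modalities, n_timepoints)
        return cls(np.ascontiguousarray(data), voxel_to_world)


@dataclass
class ChannelMaskSet:
    """Per-channel lesion masks plus the derived spatial fill/exclusion sets."""

    lesion: np.ndarray  # (X, Y, Z, n, t), bool
    prior_valid: np.ndarray | None = None  # (X, Y, Z), bool; 1 = healthy/usable

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, dtype=bool)
        if self.lesion.ndim != 5:
            raise ValueError("lesion mask array must be 5-dimensional")
        if self.prior_valid is not None:
            self.prior_valid = np.asarray(self.prior_valid, dtype=bool)
            if self.prior_valid.shape != self.lesion.shape[:3]:
                raise ValueError("prior mask grid does not match lesion masks")

    @property
    def spatial_fill_set(self) -> np.ndarray:
        """Union of all channel lesion masks: the voxels to synthesise."""
        return self.lesion.any(axis=(3, 4))

    @property
    def excluded_source_set(self) -> np.ndarray:
        """Voxels never admissible as patch-search centres."""
        excluded = self.spatial_fill_set
        if self.prior_valid is not None:
            excluded = excluded | ~self.prior_valid
        return excluded

    def channel_lesions(self) -> np.ndarray:
        """Lesion masks as (C, X, Y, Z), modality-major."""
        x, y, z, n, t = self.lesion.shape
        return np.moveaxis(self.lesion.reshape(x, y, z, n * t), -1, 0)


def load_volume(path, as_mask: bool = False):
    """Load a NIfTI volume.

    Returns ``(data, affine, voxel_size)``.  With ``as_mask=True`` the voxel
    values must be exactly {0, 1} (any NaN or other value is an error) and a
    boolean array is returned.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad input
        raise IOError(f"cannot read NIfTI file {path!r}: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    affine = np.asarray(img.affine, dtype=float)
    voxel_size = np.linalg.norm(affine[:3, :3], axis=0)
    if as_mask:
        if np.isnan(data).any():
            raise ValueError(f"NaN voxels found in mask {path!r}")
        values = np.unique(data)
        if not np.all(np.isin(values, (0.0, 1.0))):
            raise ValueError(
                f"non-binary mask {path!r}: values {values[:8]} (masks must be exactly 0/1)")
        data = data.astype(bool)
    return data, affine, voxel_size


def save_volume(data: np.ndarray, affine: np.ndarray, path, description: str = "") -> None:
    """Write ``data`` as NIfTI-1 with the given voxel-to-world affine.

    Intensity data must be finite; boolean masks are stored as uint8.
    """
    data = np.asarray(data)
    if data.dtype == bool:
        out = data.astype(np.uint8)
    else:
        if not np.all(np.isfinite(data)):
            raise ValueError("refusing to write non-finite (NaN/Inf) intensities")
        out = data.astype(np.float32)
    img = nib.Nifti1Image(out, np.asarray(affine, dtype=float))
    img.header.set_sform(affine, code=1)
    img.header.set_qform(affine, code=1)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_affine_text(path) -> np.ndarray:
    """Read a 4x4 transform from a plain-text file (4 rows x 4 floats)."""
    mat = np.loadtxt(str(path), dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"{path!r}: expected a 4x4 matrix, got shape {mat.shape}")
    return mat


def save_affine_text(matrix: np.ndarray, path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    np.savetxt(str(path), matrix, fmt="%.17g")


def _check_same_grid(shapes, affines):
    ref_shape = shapes[0]
    for s in shapes[1:]:
        if tuple(s) != tuple(ref_shape):
            raise ValueError(f"grid mismatch: shapes {tuple(ref_shape)} vs {tuple(s)}")
    affines = [a for a in affines if a is not None]
    if affines:
        ref = affines[0]
        for a in affines[1:]:
            if np.max(np.abs(np.asarray(a) - ref)) > AFFINE_TOL:
                raise ValueError("grid mismatch: voxel-to-world affines differ beyond tolerance")


def assemble_5d(volumes, masks, prior=None, affine=None, affines=None):
    """Assemble per-channel 3D volumes into a :class:`Volume5D` + masks.

    Parameters
    ----------
    volumes : sequence of (modality_index, time_index, 3D array)
        Every (n, t) slot of the grid implied by the max indices must be
        filled exactly once.
    masks : sequence of (modality_index or None, time_index, 3D bool array)
        ``modality_index=None`` shares one mask across all modalities of that
        time-point.
    prior : 3D bool array, optional
        Healthy/usable-tissue mask (1 = usable as a synthesis source).
    affine : 4x4, optional
        Common voxel-to-world transform (identity if omitted).
    affines : sequence of 4x4, optional
        Per-volume affines, checked for equality within ``AFFINE_TOL``.
    """
    if not volumes:
        raise ValueError("no volumes given")
    n_mod = max(v[0] for v in volumes) + 1
    n_tp = max(v[1] for v in volumes) + 1
    shapes = [np.asarray(v[2]).shape for v in volumes]
    _check_same_grid(shapes, affines if affines is not None else [])
    shape = shapes[0]
    if len(shape) != 3:
        raise ValueError("constituent volumes must be 3-dimensional")

    data = np.full(shape + (n_mod, n_tp), np.nan)
    seen = set()
    for n, t, vol in volumes:
        if (n, t) in seen:
            raise ValueError(f"duplicate slot (modality={n}, timepoint={t})")
        seen.add((n, t))
        data[..., n, t] = vol
    missing = [(n, t) for n in range(n_mod) for t in range(n_tp) if (n, t) not in seen]
    if missing:
        raise ValueError(f"missing slots {missing}: every (modality, timepoint) must be filled")

    lesion = np.zeros(shape + (n_mod, n_tp), dtype=bool)
    for n, t, m in masks:
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError("mask grid does not match volume grid")
        m = m.astype(bool)
        if n is None:
            lesion[..., :, t] |= m[..., None]
        else:
            lesion[..., n, t] |= m

    # intensities must be finite everywhere except where a lesion mask covers them
    maskset = ChannelMaskSet(lesion=lesion, prior_valid=prior)
    bad = ~np.isfinite(data)
    if bad.any() and not np.all(lesion[bad]):
        raise ValueError("non-finite intensities found outside the lesion masks")

    vol5d = Volume5D(data=data, voxel_to_world=affine if affine is not None else np.eye(4))
    return vol5d, maskset
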