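"""Brain-like phantoms, blob lesions and the lesion-corruption recipe.

Everything downstream is exercised on parametric phantoms generated here, so
no imaging data needs to be downloaded.  A phantom is a set of concentric
ellipsoids — background 0, an outer grey-matter ribbon, a white-matter
interior and a central CSF "ventricle" — with a periodic texture inside the
brain tissue and additive Gaussian noise.  Textures are built by modular
lookup into seeded per-axis profiles, so they are *bitwise* periodic: an
in-phase copy of a patch is float-exact, which matters when validating
exemplar-based filling.

Lesions are unions of random ellipsoidal blobs seeded in white matter and
clipped to the brain mask.  Corruption follows the standard simulated-MS
recipe: inside the lesion mask the image is multiplied voxel-wise by
0.5 × (a Gaussian noise field, rectified and min–max normalised to [0, 1]),
producing hypointense (T1-like) lesions; outside the mask the image is
bit-identical to the clean one.

Every generator is fully determined by its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .longitudinal import pairwise_from_absolute

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "generate_phantom",
    "generate_lesion_mask",
    "implant_lesions",
    "generate_longitudinal_series",
    "periodic_texture",
    "LABEL_BACKGROUND",
    "LABEL_CSF",
    "LABEL_GM",
    "LABEL_WM",
]

logger = logging.getLogger(__name__)

LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3


@dataclass
class PhantomSpec:
    """Parameters of the multi-tissue phantom.

    ``tissue_means`` default to a T1-like ordering CSF < GM < WM (arbitrary
    intensity units); pass a reversed ordering for T2/PD-like contrast.
    ``texture_amplitude`` is a fraction of the WM mean; ``noise_sigma`` is in
    intensity units.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    tissue_means: dict = field(default_factory=lambda: {"CSF": 30.0, "GM": 90.0, "WM": 140.0})
    texture_amplitude: float = 0.05
    texture_period: int = 8
    noise_sigma: float = 3.0
    seed: int = 0


@dataclass
class LesionSpec:
    """Parameters of the blob-lesion generator."""

    n_blobs: int = 3
    radius_range: tuple[float, float] = (2.0, 3.5)
    placement: str = "WM-only"  # or "periventricular-biased"
    seed: int = 0


def periodic_texture(shape, period: int, seed: int = 0,
                     amplitude: float = 1.0) -> np.ndarray:
    """Separable, bitwise-periodic texture: tx[x % P] + ty[y % P] + tz[z % P].

    Profiles are seeded uniform draws in [-1, 1] (generically injective over
    a period), scaled so the texture lies in [-amplitude, amplitude].
    """
    rng = np.random.default_rng(seed)
    profiles = rng.uniform(-1.0, 1.0, size=(3, period))
    idx = [np.arange(s) % period for s in shape]
    tex = (profiles[0][idx[0]][:, None, None]
           + profiles[1][idx[1]][None, :, None]
           + profiles[2][idx[2]][None, None, :])
    return tex * (amplitude / 3.0)


def _ellipsoid(shape, centre, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, a in zip(grids, centre, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Build the phantom.  Returns ``(image, labels, brain_mask)``.

    Geometry: brain ellipsoid (semi-axes 0.42 × shape) containing an outer GM
    ribbon, a WM interior and a central ellipsoidal CSF ventricle.
    """
    shape = tuple(spec.shape)
    if min(shape) < 32:
        raise ValueError("phantom shape must be at least 32 voxels per axis")
    centre = [(s - 1) / 2.0 for s in shape]
    brain_ax = [0.42 * s for s in shape]
    inner_ax = [0.80 * a for a in brain_ax]
    vent_ax = [0.18 * s for s in shape]

    brain = _ellipsoid(shape, centre, brain_ax)
    inner = _ellipsoid(shape, centre, inner_ax)
    vent = _ellipsoid(shape, centre, vent_ax)

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.int8)
    labels[brain & ~inner] = LABEL_GM
    labels[inner & ~vent] = LABEL_WM
    labels[vent] = LABEL_CSF

    image = np.zeros(shape)
    image[labels == LABEL_CSF] = spec.tissue_means["CSF"]
    image[labels == LABEL_GM] = spec.tissue_means["GM"]
    image[labels == LABEL_WM] = spec.tissue_means["WM"]

    if spec.texture_amplitude > 0:
        tex = periodic_texture(shape, spec.texture_period, seed=spec.seed,
                               amplitude=spec.texture_amplitude * spec.tissue_means["WM"])
        tissue = (labels == LABEL_WM) | (labels == LABEL_GM)
        image[tissue] += tex[tissue]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        noise = rng.normal(0.0, spec.noise_sigma, size=shape)
        image[brain] += noise[brain]
    return image, labels, brain


def generate_lesion_mask(labels: np.ndarray, brain_mask: np.ndarray,
                         spec: LesionSpec) -> np.ndarray:
    """Union of random ellipsoidal blobs centred in WM, clipped to the brain."""
    wm = labels == LABEL_WM
    if not wm.any():
        raise ValueError("no white matter in the label map")
    rng = np.random.default_rng(spec.seed)
    if spec.placement == "periventricular-biased":
        # favour WM voxels close to the ventricle surface
        vent_dist = ndimage.distance_transform_edt(labels != LABEL_CSF)
        weights = np.where(wm, 1.0 / (1.0 + vent_dist), 0.0)
    else:
        weights = wm.astype(float)
    coords = np.argwhere(weights > 0)
    probs = weights[weights > 0]
    probs = probs / probs.sum()

    mask = np.zeros(labels.shape, dtype=bool)
    placed = 0
    for _ in range(spec.n_blobs):
        centre = coords[rng.choice(len(coords), p=probs)]
        radii = rng.uniform(*spec.radius_range, size=3)
        blob = _ellipsoid(labels.shape, centre, radii) & brain_mask
        if blob.any():
            mask |= blob
            placed += 1
    if placed < spec.n_blobs:
        logger.warning("placed only %d of %d requested lesion blobs",
                       placed, spec.n_blobs)
    return mask


def implant_lesions(image: np.ndarray, lesion_mask: np.ndarray, seed: int = 0):
    """Corrupt the image inside the lesion mask.

    The intensity profile is 0.5 × |N(0,1)| min–max normalised to [0, 1] over
    the mask (1 outside), and the output is ``image × profile`` — so in-mask
    intensities drop to [0, 0.5] of their clean values and everything outside
    is untouched.  Returns ``(corrupted, profile)``.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    if lesion_mask.shape != image.shape:
        raise ValueError("lesion mask grid does not match the image")
    profile = np.ones(image.shape)
    n = int(lesion_mask.sum())
    if n:
        rng = np.random.default_rng(seed)
        noise = np.abs(rng.standard_normal(n))
        span = noise.max() - noise.min()
        normed = (noise - noise.min()) / span if span > 0 else np.zeros(n)
        profile[lesion_mask] = 0.5 * normed
    corrupted = image * profile
    return corrupted, profile


def _rigid_affine(rng: np.random.Generator, max_shift: float,
                  max_angle: float) -> np.ndarray:
    """Small random rigid transform (voxel coordinates, rotation about z)."""
    angle = rng.uniform(-max_angle, max_angle)
    shift = rng.uniform(-max_shift, max_shift, size=3)
    mat = np.eye(4)
    ca, sa = np.cos(angle), np.sin(angle)
    mat[:2, :2] = [[ca, -sa], [sa, ca]]
    mat[:3, 3] = shift
    return mat


def generate_longitudinal_series(spec: PhantomSpec, n_timepoints: int = 2,
                                 atrophy_scale: float = 0.0,
                                 lesion_change: int = 0,
                                 max_shift: float = 1.5,
                                 max_angle: float = 0.05,
                                 lesion_spec: LesionSpec | None = None):
    """Simulate one subject scanned at several time-points.

    Each time-point is the base phantom under a small random rigid motion
    (time-point 0 stays in the reference frame), with optional ventricle
    dilation (``atrophy_scale`` extra dilation steps per time-point) and
    lesion growth (``lesion_change`` dilation steps per time-point).  The
    ground-truth pairwise transforms T_{i,j} = A_j^-1 A_i are exported with
    the series.

    Returns ``(timepoints, pairwise)`` where ``timepoints`` is a list of
    dicts with keys ``image``, ``mask``, ``labels``, ``brain`` and
    ``pairwise`` maps (i, j) to 4x4 matrices.
    """
    if n_timepoints < 2:
        raise ValueError("a longitudinal series needs at least 2 time-points")
    rng = np.random.default_rng(spec.seed + 1000)
    lesion_spec = lesion_spec or LesionSpec(seed=spec.seed + 2000)

    base_image, base_labels, base_brain = generate_phantom(spec)
    base_mask = generate_lesion_mask(base_labels, base_brain, lesion_spec)

    absolute = [np.eye(4)]
    for _ in range(1, n_timepoints):
        absolute.append(_rigid_affine(rng, max_shift, max_angle))
    pairwise = pairwise_from_absolute(absolute)

    timepoints = []
    for t in range(n_timepoints):
        labels = base_labels.copy()
        image = base_image.copy()
        if atrophy_scale > 0 and t > 0:
            vent = ndimage.binary_dilation(labels == LABEL_CSF,
                                           iterations=int(round(atrophy_scale * t)))
            grown = vent & (labels == LABEL_WM)
            labels[grown] = LABEL_CSF
            image[grown] = spec.tissue_means["CSF"]
        mask = base_mask.copy()
        if lesion_change > 0 and t > 0:
            mask = ndimage.binary_dilation(mask, iterations=lesion_change * t)
            mask &= base_brain
        corrupted, _ = implant_lesions(image, mask, seed=spec.seed + 3000)

        if t == 0:
            img_t, mask_t, labels_t, brain_t = corrupted, mask, labels, base_brain
        else:
            # move into the time-point's own frame: native(x) = ref(A_t x)
            a = absolute[t]
            img_t = ndimage.affine_transform(corrupted, a[:3, :3], offset=a[:3, 3],
                                             order=1, mode="constant", cval=0.0)
            mask_t = ndimage.affine_transform(mask.astype(float), a[:3, :3],
                                              offset=a[:3, 3], order=0) > 0.5
            labels_t = ndimage.affine_transform(labels.astype(float), a[:3, :3],
                                                offset=a[:3, 3], order=0).astype(np.int8)
            brain_t = ndimage.affine_transform(base_brain.astype(float), a[:3, :3],
                                               offset=a[:3, 3], order=0) > 0.5
        timepoints.append({"image": img_t, "mask": mask_t,
                           "labels": labels_t, "brain": brain_t})
    return timepoints, pairwise
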