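# Methods

## The filling model

`lesionfill` treats lesion filling as exemplar-based image completion. The
input is a 5D stack I\*(x, y, z, n, t) of n modalities over t time-points on
one spatial grid, each channel with a binary lesion mask; the spatial union
of all channel masks is the *fill set*. For every fill-set voxel p the
method searches a cubic window Ω of side W around p for the source centre

    q̂ = argmin_{q ∈ Ω, q ≠ p, q ∉ excluded}  D(T(p), S(q)),
    D(T, S) = Σ_i (I(p+i) − I(q+i))² / κ^c,

where T(p) and S(q) are 5D patches of n·t·w³ voxels and the sum runs over
the κ channel-offsets at which *both* patch voxels are valid. κ^c with
c > 1 penalises matches supported by few valid voxels. A candidate is
accepted only under the hard constraint κ > α·n·t·w³. On acceptance, the
intensity at q̂ is copied into every lesioned channel at p — a single shared
source per voxel, which keeps synthesised texture consistent across
modalities and time-points — and p is marked solved.

Assumptions: the image contains repetitive local texture so that plausible
exemplars exist within W of each lesion; channels are co-registered on one
grid; lesion masks may over-segment (the contextual search tolerates this)
but must cover the abnormal tissue, since in-mask intensities are never
trusted.

### Validity bookkeeping

A voxel-channel (r, n, t) is valid for the distance sum iff r is currently
outside the (shrinking) lesion set of that channel and in bounds. Solved
voxels immediately become valid, so the concentric schedule lets freshly
synthesised boundary texture support deeper voxels. Out-of-bounds patch
voxels are treated as invalid (dropped from κ) rather than padded.
Prior-invalid voxels that are not lesioned count as *valid* in the distance
sum — the prior only removes them from the set of admissible centres q and
widens the adaptive patch via the distance map. Candidate centres are drawn
from the static excluded-source set (original lesions ∪ prior-invalid), so
sources are always observed, never synthesised, voxels.

### Processing order and termination

Each pass orders the remaining unsolved voxels by increasing Euclidean
distance to the nearest usable voxel (boundary first, ties lexicographic by
(z, y, x) for cross-platform determinism) and scans them once. A pass that
solves nothing multiplies α by `alpha_relax_factor` (default 0.5) and logs a
warning; this guarantees termination on inputs where the initial α is
unreachable (e.g. a lesion larger than any fully valid patch), while leaving
non-degenerate runs untouched. After `max_passes` (default 100) the fill
aborts with an error rather than returning a partial result. Note that
α = 1.0 is *never* satisfiable for a lesioned target — the target's own
centre voxel is invalid, so κ ≤ n·t·w³ − 1 — and immediately triggers
relaxation; this follows from the strict inequality in the constraint.

### Buffing

After all voxels are solved, each originally-lesioned voxel is replaced by a
normalised 6-neighbour cross-kernel combination of the filled image (centre
weight 1, face-neighbours K, scaled to sum 1; at image borders, missing
neighbours are dropped and the kernel renormalised). Buffing is applied
out-of-place (one convolution of the filled image) and only inside the
original lesion, so observed data are never perturbed. K = 0 makes buffing
the identity.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| α | 0.5 | fraction | minimum valid fraction κ/(n·t·w³) of a usable match |
| K | 0.1 | – | buffing kernel neighbour weight |
| c | 2 | – | exponent of the κ information penalty |
| w | adaptive | voxels | patch side: max over lesion voxels of dist+1, rounded up to odd ≥ 3 |
| W | 4w (oddified) | voxels | search window side |
| `max_passes` | 100 | – | hard termination bound |
| `alpha_relax_factor` | 0.5 | – | α multiplier on a stalled pass |

The adaptive w is computed *globally* (one value per problem, the maximum
over the fill set) rather than per voxel; `patch_side_override` exposes the
alternative. Distances for sizing and scheduling are computed in isotropic
index space — anisotropic voxel sizes are ignored, which only ever
overestimates w. The distance map runs against the full excluded-source
set, so a restrictive prior widens patches.

## Longitudinal mean space

Registration is out of scope: pairwise affine matrices T_{i,j} (voxel
coordinates, image i → image j; positive-determinant 3×3 block) are inputs.
The average space for image i is T_{h,i} = exp((1/N) Σ_j log T_{i,j}), using
the principal matrix logarithm (guarded: a non-real logarithm or negative
determinant is an error). The average grid is the first time-point's grid;
intensities are resampled trilinearly, masks by nearest neighbour with > 0.5
binarisation. Output defaults to the average space (where downstream
atrophy pipelines operate on aligned scans); `native=True` inverse-resamples
each filled channel. Per-time-point masks are kept distinct throughout, so
lesions may appear, grow or shrink across time-points.

## Synthetic data

The phantom generator emulates the structure a filling method actually
interacts with, not MR physics: concentric ellipsoids (background 0, outer
GM ribbon, WM interior, central CSF "ventricle"; brain semi-axes 0.42 ×
shape), T1-like default means CSF 30 < GM 90 < WM 140 (arbitrary units), a
separable periodic texture inside GM/WM (amplitude 5% of the WM mean,
period 8 voxels) and additive Gaussian noise inside the brain (σ = 3, i.e.
~2% of the WM mean). Textures are built by modular lookup into seeded
per-axis profiles, making them bitwise periodic — an in-phase patch copy is
float-exact, so exact-recovery tests are meaningful at float precision.

Lesions are unions of random ellipsoidal blobs (default 3 blobs, radii
1.5–3.5 voxels) centred in WM — optionally biased towards the ventricle
surface — and clipped to the brain mask. Corruption multiplies in-mask
intensities by 0.5 × a rectified, min–max-normalised Gaussian noise field
(profile in [0, 0.5], hypointense T1-like lesions); the exact in-mask recipe
is cosmetic since the method never reads in-mask values, and the corrupted
image is bit-identical to the clean one outside the mask. The longitudinal
generator adds small rigid motions per time-point (exporting the exact
pairwise transforms T_{i,j} = A_j⁻¹A_i), optional ventricle dilation
("atrophy") and lesion growth; the corruption noise field is drawn once per
series so time-point differences come only from the modelled changes.

What passing on phantoms does *not* show: robustness to bias fields,
partial-volume boundaries, real anatomical texture statistics, registration
error (transforms here are exact), or real lesion morphology. The phantoms
validate the algorithmic contracts, not clinical performance.

## Evaluation conventions

Before entropy/gradient/MSE, images are normalised by a robust 1st–99th
percentile min-max over the brain mask (clipped to [0, 1]); the filled image
is normalised with the clean image's percentiles so the two are comparable.
Entropy uses 64 equal-width bins over [0, 1], normalised by log 64. The
boundary gradient is the mean central-difference gradient magnitude over the
1-voxel shell just outside the lesion. Both conventions are recorded in
every report. Tissue volumes for ME = 100 (V_T − V_0)/V_0 come from the
phantom's ground-truth labels: since segmentation tools are out of scope,
the post-filling volume re-classifies only in-lesion voxels, assigning each
to the tissue whose mean intensity (estimated outside the lesions from the
ground-truth labels) is nearest; all other voxels keep their true label.
This isolates the volume bias introduced by the synthesised intensities.

## Numerical and design choices

- All tie-breaks (argmin over candidates, schedule order) are lexicographic
  in (z, y, x); the core contains no randomness, so runs are bit-identical.
- κ = 0 candidate pairs get D = +∞ rather than raising, letting the scan
  continue past them.
- The optimised scan gathers candidate patches through a zero-padded,
  validity-padded stack in fixed-size chunks; it is verified voxel-exact
  against a literal per-candidate reference implementation in the tests.
- Masks must be exactly {0, 1} on load; resampled masks are binarised at
  > 0.5. Grid equality tolerates 1e-4 on affine entries (float32 header
  noise).
- The study sizes used by the test suite and `scripts/acceptance.py`
  (five 44³ phantoms, ~150–250 lesion voxels each) were chosen as the
  smallest cohort on which the patch-vs-baseline comparison and the
  per-tissue volume-error bounds are stable across seeds.

## Known limitations

- Exhaustive window scanning is O(W³·w³·n·t) per voxel; very large lesions
  (big adaptive w) are slow. The original large-lesion escape hatches —
  multi-resolution search, candidate subsampling — are deliberately not
  implemented.
- Weighted averaging of several good matches is deliberately rejected
  (single-best-copy preserves noise statistics; averaging blurs).
- One lesion mask per channel is the general case; sharing one mask across
  modalities of a time-point is supported, but cross-modality mask conflicts
  are not reconciled automatically.
- The prior cannot rescue a lesion whose entire search window is excluded;
  such runs stall through α-relaxation and fail at `max_passes`.
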