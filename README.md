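# lesionfill

Patch-based, modality-agnostic, multi-time-point filling of multiple
sclerosis lesions in MR images.

MS lesions bias tissue segmentation and atrophy measurement: most pipelines
therefore "fill" segmented lesions with synthetic normal-appearing tissue
before morphometry. Classical fillers replace lesions with white-matter-like
intensities from a global or local intensity model, which fails for
periventricular lesions, over-segmented masks, and non-T1 contrasts.
`lesionfill` instead treats filling as exemplar-based in-painting: each
lesion voxel is replaced by copying the intensity at the centre of the most
similar *patch* of observed tissue, searched non-locally around the lesion —
jointly across all modalities and time-points of a subject.

## Method

All channels (n modalities × t time-points, co-registered) form a 5D stack
I\*. For a lesion voxel p, processed concentrically from the lesion boundary
inwards, the source voxel is

&nbsp;&nbsp;&nbsp;&nbsp;q̂ = argmin_{q ∈ Ω, q ≠ p, q ∉ L} D(T(p), S(q)),
&nbsp;&nbsp;&nbsp;&nbsp;D = Σᵢ (I(p+i) − I(q+i))² / κᶜ,

where T, S are 5D patches of n·t·w³ voxels, the sum runs over the κ
channel-offsets at which both patch voxels are valid (outside the current
lesion set and in bounds), and κᶜ (c > 1) favours information-rich matches.
A candidate is accepted only if κ > α·n·t·w³. On success, I\*(q̂) is copied
into *every* lesioned channel at p (one shared q̂ — consistent texture
across time-points and modalities), and p becomes valid for later patches.
The patch side adapts to lesion thickness, w = max_r dist(r) + 1 over lesion
voxels r (rounded up to odd), with search window W = 4w. Filled regions are
finally "buffed" with a normalised 6-neighbour cross kernel (centre 1,
neighbours K, scaled to sum 1). Defaults: α = 0.5, K = 0.1, c = 2.

For longitudinal input the time-points are first brought into an unbiased
mean space via the log-Euclidean mean of pairwise affine transforms,
T_{h,i} = exp((1/N) Σⱼ log T_{i,j}), then filled jointly.

An optional *prior* mask of usable tissue restricts where sources may be
drawn from (and widens the adaptive patch accordingly) without affecting
the patch-distance bookkeeping.

The package also ships the validation apparatus: parametric multi-tissue
brain phantoms with bitwise-periodic texture, blob-lesion simulation with
the ×0.5 noise-profile corruption recipe, and the metric battery
(normalised entropy, boundary |∇I|, synthesis MSE, per-tissue volume error
ME/MAE).

## Worked example

```python
import numpy as np
from lesionfill import (PhantomSpec, LesionSpec, generate_phantom,
                        generate_lesion_mask, implant_lesions, assemble_5d,
                        inpaint_5d, apply_buffing, make_buff_kernel,
                        evaluation_report)

spec = PhantomSpec(shape=(44, 44, 44), noise_sigma=3.0, seed=1)
clean, labels, brain = generate_phantom(spec)
mask = generate_lesion_mask(labels, brain, LesionSpec(n_blobs=3, seed=2))
lesioned, _ = implant_lesions(clean, mask, seed=3)

volume, masks = assemble_5d([(0, 0, lesioned)], [(0, 0, mask)], prior=brain)
filled, log = inpaint_5d(volume, masks)
filled = apply_buffing(filled, masks, make_buff_kernel(0.1))

report = evaluation_report(filled.data[:, :, :, 0, 0], clean, mask, labels,
                           brain_mask=brain)
print(f"{len(log)} voxels filled, MSE={report.mse:.5f}, "
      f"ME(WM)={report.me_per_tissue['WM']:+.3f}%")
```

prints

```
207 voxels filled, MSE=0.00619, ME(WM)=+0.061%
```

i.e. all 207 lesion voxels were synthesised, the filled intensities differ
from the true (pre-corruption) tissue by a mean squared error of 0.006 on
the normalised [0, 1] intensity scale, and the filling shifted the
white-matter volume by only +0.06%.

The same pipeline is available from the shell:

```bash
lesionfill simulate --seed 3 -o sim/
lesionfill fill -i sim/lesioned.nii.gz -m sim/mask.nii.gz -o filled.nii.gz
lesionfill evaluate --filled filled.nii.gz --truth sim/clean.nii.gz \
    --mask sim/mask.nii.gz --labels sim/labels.nii.gz -o report.json
```

plus `lesionfill fill-long` for joint multi-time-point filling from a
manifest CSV and a directory of pairwise `T_<i>_<j>.txt` transforms. Every
run writes a JSON provenance sidecar with its full effective configuration.

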