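"""Quality metrics for filled lesions.

Four complementary views of a filling result:

* **normalised entropy** of the in-lesion intensity histogram — tissue
  homogeneity (0 = one intensity everywhere, 1 = uniform over all bins);
* **boundary gradient magnitude** — mean |∇I| over the one-voxel shell just
  outside the lesion, exposing spurious edges at the fill boundary;
* **synthesis MSE** against the known clean image inside the lesion;
* **tissue volume error** ME = 100·(V_T − V_0)/V_0 per tissue class, and its
  absolute value MAE, measuring how filling shifts tissue classification.

Intensities are normalised with a robust 1st–99th percentile min-max (over
the brain mask when given) before entropy/gradient/MSE, and histograms use
64 equal-width bins over [0, 1]; both conventions are recorded in every
report.  Tissue volumes come from the phantom's ground-truth label map:
after filling, only in-lesion voxels are re-classified, by nearest tissue
mean (means estimated from the clean image outside the lesions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import ndimage

from .synthetic import LABEL_CSF, LABEL_GM, LABEL_WM

__all__ = [
    "MetricConfig",
    "EvalReport",
    "normalize_intensity",
    "normalized_entropy",
    "boundary_gradient_magnitude",
    "synthesis_mse",
    "volume_error",
    "classify_filled_tissue",
    "evaluation_report",
]

TISSUE_LABELS = {"CSF": LABEL_CSF, "GM": LABEL_GM, "WM": LABEL_WM}


@dataclass
class MetricConfig:
    n_bins: int = 64
    percentiles: tuple[float, float] = (1.0, 99.0)
    gradient_operator: str = "central-difference"
    boundary_shell: str = "1-voxel outer morphological gradient"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 histogram bins")


@dataclass
class EvalReport:
    entropy: float
    boundary_gradient: float
    mse: float
    me_per_tissue: dict
    mae_per_tissue: dict
    n_lesion_voxels: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def normalize_intensity(image: np.ndarray, mask: np.ndarray | None,
                        config: MetricConfig,
                        reference: np.ndarray | None = None) -> np.ndarray:
    """Robust percentile min-max normalisation, clipped to [0, 1].

    Percentiles are taken over ``reference`` (default: the image itself)
    restricted to ``mask`` when given.
    """
    ref = image if reference is None else reference
    sample = ref[np.asarray(mask, bool)] if mask is not None else ref.ravel()
    lo, hi = np.percentile(sample, config.percentiles)
    if hi <= lo:
        return np.zeros_like(image, dtype=float)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def normalized_entropy(image: np.ndarray, mask: np.ndarray,
                       config: MetricConfig | None = None) -> float:
    """Shannon entropy of the in-mask histogram, normalised by log(n_bins)."""
    config = config or MetricConfig()
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    values = image[mask]
    counts, _ = np.histogram(values, bins=config.n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(config.n_bins))


def boundary_gradient_magnitude(image: np.ndarray, mask: np.ndarray,
                                config: MetricConfig | None = None) -> float:
    """Mean central-difference |∇I| over the 1-voxel shell outside the mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    shell = ndimage.binary_dilation(mask) & ~mask
    if not shell.any():
        raise ValueError("empty boundary shell")
    grads = np.gradient(np.asarray(image, float))
    mag = np.sqrt(sum(g ** 2 for g in grads))
    return float(mag[shell].mean())


def synthesis_mse(filled: np.ndarray, ground_truth: np.ndarray,
                  mask: np.ndarray) -> float:
    """Mean squared difference over in-mask voxels (inputs already on a
    common intensity scale)."""
    filled, truth = np.asarray(filled, float), np.asarray(ground_truth, float)
    if filled.shape != truth.shape:
        raise ValueError("grid mismatch between filled image and ground truth")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = filled[mask] - truth[mask]
    return float(np.mean(diff ** 2))


def volume_error(v_after: float, v_before: float) -> float:
    """Signed tissue-volume error ME = 100 (V_T − V_0) / V_0, in percent."""
    if v_before <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * (v_after - v_before) / v_before


def classify_filled_tissue(filled: np.ndarray, labels: np.ndarray,
                           lesion_mask: np.ndarray) -> np.ndarray:
    """Re-classify in-lesion voxels of the filled image by nearest tissue mean.

    Tissue means are estimated from the image outside the lesions using the
    ground-truth labels; all other voxels keep their ground-truth label.
    """
    lesion_mask = np.asarray(lesion_mask, bool)
    out = np.asarray(labels).copy()
    names, means = [], []
    for name, lab in TISSUE_LABELS.items():
        sel = (labels == lab) & ~lesion_mask
        if sel.any():
            names.append(lab)
            means.append(float(filled[sel].mean()))
    if not names:
        raise ValueError("no healthy tissue voxels to calibrate the classifier")
    means = np.asarray(means)
    vals = filled[lesion_mask]
    nearest = np.argmin(np.abs(vals[:, None] - means[None, :]), axis=1)
    out[lesion_mask] = np.asarray(names)[nearest]
    return out


def evaluation_report(filled: np.ndarray, truth: np.ndarray,
                      lesion_mask: np.ndarray, labels: np.ndarray,
                      brain_mask: np.ndarray | None = None,
                      config: MetricConfig | None = None) -> EvalReport:
    """Aggregate all metrics for one filled image against its ground truth."""
    config = config or MetricConfig()
    lesion_mask = np.asarray(lesion_mask, bool)
    norm_mask = brain_mask if brain_mask is not None else None
    truth_n = normalize_intensity(truth, norm_mask, config)
    filled_n = normalize_intensity(filled, norm_mask, config, reference=truth)

    entropy = normalized_entropy(filled_n, lesion_mask, config)
    gradient = boundary_gradient_magnitude(filled_n, lesion_mask, config)
    mse = synthesis_mse(filled_n, truth_n, lesion_mask)

    relabelled = classify_filled_tissue(filled, labels, lesion_mask)
    me, mae = {}, {}
    for name, lab in TISSUE_LABELS.items():
        v0 = int((labels == lab).sum())
        if v0 == 0:
            continue
        vt = int((relabelled == lab).sum())
        me[name] = volume_error(vt, v0)
        mae[name] = abs(me[name])

    return EvalReport(entropy=entropy, boundary_gradient=gradient, mse=mse,
                      me_per_tissue=me, mae_per_tissue=mae,
                      n_lesion_voxels=int(lesion_mask.sum()),
                      config=asdict(config))
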