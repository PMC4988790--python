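"""The exemplar-based 5D patch fill: κ^c-weighted patch distance, constrained
best-match search, multi-pass concentric filling, and the final buffing pass.

For each lesion voxel ``p`` (processed boundary-first) the algorithm scans a
window Ω of side ``W`` around ``p`` for the source centre

    q̂ = argmin_{q ∈ Ω, q ≠ p, q ∉ excluded} D(T(p), S(q)),

where ``T``/``S`` are 5D patches of ``n·t·w³`` voxels and

    D = Σ_i (I(p+i) − I(q+i))² / κ^c

with the sum restricted to channel-offsets ``i`` at which both patch voxels
are currently valid (not lesioned, in bounds); ``κ`` counts those offsets
and ``κ^c`` (c > 1) favours information-rich matches.  A match is accepted
only under the hard constraint ``κ > α·n·t·w³``.  On success the intensity
at q̂ is copied into every lesioned channel at ``p`` — one shared q̂ across
modalities and time-points — and ``p`` becomes valid for later patches.

Voxels excluded by a prior mask are never admissible as centres ``q`` but do
contribute to patch distances, so priors steer sourcing without starving κ.

A pass that solves nothing (the α constraint is unreachable, e.g. a huge
lesion in a tiny valid region) halves α and retries; the loop errors out
after ``max_passes``.  Finally the filled region is "buffed" with a
normalised 6-neighbour cross kernel to remove spurious edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (adaptive_patch_width, nonlesion_distance_map,
                       patch_offsets, processing_schedule, search_window_side)
from .io_volumes import ChannelMaskSet, Volume5D

__all__ = [
    "FillParams",
    "MatchResult",
    "FillRecord",
    "make_buff_kernel",
    "patch_distance",
    "find_best_match",
    "inpaint_5d",
    "apply_buffing",
    "write_fill_log",
]

logger = logging.getLogger(__name__)


@dataclass
class FillParams:
    """Tunable parameters of the fill.

    Defaults are the method's standard settings: α = 0.5 (a candidate patch
    pair must share >50% valid voxels), K = 0.1 (buffing kernel weight),
    c = 2 (κ^c information penalty), W = 4w search window.
    """

    alpha: float = 0.5
    kernel_k: float = 0.1
    c: float = 2.0
    window_multiplier: int = 4
    patch_side_override: int | None = None
    max_passes: int = 100
    alpha_relax_factor: float = 0.5
    tie_break: str = "first-in-scan-order"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.kernel_k < 0:
            raise ValueError("kernel_k must be >= 0")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if not 0.0 < self.alpha_relax_factor < 1.0:
            raise ValueError("alpha_relax_factor must lie in (0, 1)")


@dataclass
class MatchResult:
    """Outcome of one best-match search."""

    q_hat: tuple[int, int, int] | None
    distance: float
    kappa: int
    satisfied_constraint: bool


@dataclass
class FillRecord:
    """One solved voxel in the fill log."""

    p: tuple[int, int, int]
    q: tuple[int, int, int]
    distance: float
    kappa: int
    pass_number: int


def make_buff_kernel(kernel_k: float) -> np.ndarray:
    """Normalised 3x3x3 cross kernel: centre 1, the 6 face-neighbours K,
    everything else 0, scaled to sum to 1."""
    if kernel_k < 0:
        raise ValueError("kernel weight K must be >= 0")
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = 1.0
    for axis in range(3):
        for delta in (0, 2):
            idx = [1, 1, 1]
            idx[axis] = delta
            kernel[tuple(idx)] = kernel_k
    return kernel / kernel.sum()


def _candidate_coords(centre, window_side, shape):
    """All voxels of the clipped window in lexicographic (z, y, x) order."""
    h = window_side // 2
    ranges = [np.arange(max(0, c - h), min(s, c + h + 1))
              for c, s in zip(centre, shape)]
    zz, yy, xx = np.meshgrid(ranges[2], ranges[1], ranges[0], indexing="ij")
    return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)


def patch_distance(channels: np.ndarray, valid: np.ndarray,
                   p, q, side: int, c: float = 2.0) -> tuple[float, int]:
    """Literal κ^c patch distance between the patches centred at p and q.

    ``channels``: (C, X, Y, Z) intensity stack; ``valid``: matching boolean
    stack (False inside the current lesion set).  Returns (D, κ); κ = 0
    yields D = +inf.
    """
    offs = patch_offsets(side)
    shape = channels.shape[1:]
    tpos = np.asarray(p)[None, :] + offs
    spos = np.asarray(q)[None, :] + offs
    t_in = np.all((tpos >= 0) & (tpos < np.asarray(shape)[None, :]), axis=1)
    s_in = np.all((spos >= 0) & (spos < np.asarray(shape)[None, :]), axis=1)
    both = t_in & s_in
    tpos_c, spos_c = tpos[both], spos[both]
    tvals = channels[:, tpos_c[:, 0], tpos_c[:, 1], tpos_c[:, 2]]
    svals = channels[:, spos_c[:, 0], spos_c[:, 1], spos_c[:, 2]]
    tval = valid[:, tpos_c[:, 0], tpos_c[:, 1], tpos_c[:, 2]]
    sval = valid[:, spos_c[:, 0], spos_c[:, 1], spos_c[:, 2]]
    joint = tval & sval
    kappa = int(joint.sum())
    if kappa == 0:
        return float("inf"), 0
    ssd = float((((tvals - svals) ** 2) * joint).sum())
    return ssd / kappa ** c, kappa


class _PatchScanner:
    """Vectorised best-match scanning over a padded channel stack.

    Pads image and validity by ``side // 2`` so patch gathers never index out
    of bounds; padded voxels carry valid=False, which reproduces the rule
    that out-of-bounds patch voxels are dropped from the κ set.
    """

    def __init__(self, channels: np.ndarray, valid: np.ndarray, side: int,
                 window_side: int):
        self.side = side
        self.window_side = window_side
        self.shape = channels.shape[1:]
        self.h = side // 2
        pad = [(0, 0)] + [(self.h, self.h)] * 3
        self.channels = np.pad(channels, pad)
        self.valid = np.pad(valid, pad, constant_values=False)
        self.offsets = patch_offsets(side) + self.h  # into padded arrays

    def set_valid(self, pos, value: bool) -> None:
        self.valid[:, pos[0] + self.h, pos[1] + self.h, pos[2] + self.h] = value

    def _gather(self, coords):
        """Patch values/validity for centres ``coords`` → (Q, C, w³)."""
        pos = coords[:, None, :] + self.offsets[None, :, :]
        vals = self.channels[:, pos[..., 0], pos[..., 1], pos[..., 2]]
        val = self.valid[:, pos[..., 0], pos[..., 1], pos[..., 2]]
        return np.moveaxis(vals, 0, 1), np.moveaxis(val, 0, 1)

    def best_match(self, p, admissible: np.ndarray, alpha: float, c: float,
                   chunk: int = 4096) -> MatchResult:
        """Exhaustive constrained argmin over the window around ``p``.

        ``admissible`` is the static spatial mask of allowed centres q
        (outside the excluded-source set); p itself is always excluded.
        Ties keep the first candidate in lexicographic (z, y, x) order.
        """
        coords = _candidate_coords(p, self.window_side, self.shape)
        keep = admissible[coords[:, 0], coords[:, 1], coords[:, 2]]
        keep &= ~np.all(coords == np.asarray(p)[None, :], axis=1)
        coords = coords[keep]
        if coords.shape[0] == 0:
            return MatchResult(None, float("inf"), 0, False)

        tvals, tvalid = self._gather(np.asarray(p)[None, :])
        n_total = tvals.shape[1] * tvals.shape[2]  # n·t·w³
        threshold = alpha * n_total

        best_d, best_kappa, best_q = np.inf, 0, None
        for start in range(0, coords.shape[0], chunk):
            block = coords[start:start + chunk]
            svals, svalid = self._gather(block)
            joint = tvalid & svalid  # (Q, C, w³)
            kappa = joint.sum(axis=(1, 2))
            ssd = (((tvals - svals) ** 2) * joint).sum(axis=(1, 2))
            denom = np.where(kappa > 0, kappa.astype(float), 1.0) ** c
            d = np.where(kappa > 0, ssd / denom, np.inf)
            d = np.where(kappa > threshold, d, np.inf)
            i = int(np.argmin(d))
            if d[i] < best_d:  # strict: first-in-scan-order tie rule
                best_d = float(d[i])
                best_kappa = int(kappa[i])
                best_q = tuple(int(v) for v in block[i])
        if best_q is None:
            return MatchResult(None, float("inf"), 0, False)
        return MatchResult(best_q, best_d, best_kappa, True)


def find_best_match(channels: np.ndarray, valid: np.ndarray, p, side: int,
                    window_side: int, admissible: np.ndarray,
                    params: FillParams) -> MatchResult:
    """Best admissible source centre for target ``p`` (see module docstring)."""
    scanner = _PatchScanner(channels, valid, side, window_side)
    return scanner.best_match(tuple(p), admissible, params.alpha, params.c)


def inpaint_5d(volume: Volume5D, maskset: ChannelMaskSet,
               params: FillParams | None = None
               ) -> tuple[Volume5D, list[FillRecord]]:
    """Multi-pass concentric fill of every lesion voxel (pre-buffing).

    Each pass orders the remaining unsolved voxels boundary-first and scans
    for each one; solved voxels immediately become valid patch content for
    the voxels that follow.  Returns the filled stack and the fill log.
    """
    params = params or FillParams()
    channels = np.ascontiguousarray(volume.channels().astype(np.float64))
    lesions = maskset.channel_lesions()
    fill_set = maskset.spatial_fill_set
    excluded = maskset.excluded_source_set
    if not fill_set.any():
        raise ValueError("empty fill set")
    if excluded.all():
        raise ValueError("excluded set covers the entire image: nothing to copy from")

    prior_invalid = (~maskset.prior_valid if maskset.prior_valid is not None
                     else np.zeros(fill_set.shape, dtype=bool))
    admissible = ~excluded  # static: solved lesion voxels never become centres

    if params.patch_side_override is not None:
        side = params.patch_side_override
        if side < 3 or side % 2 == 0:
            raise ValueError("patch_side_override must be odd and >= 3")
    else:
        dist = nonlesion_distance_map(excluded)
        side = adaptive_patch_width(dist, fill_set)
    window = search_window_side(side, params.window_multiplier)

    # lesion voxels invalid until solved; out-of-bounds handled by padding
    valid = ~lesions
    scanner = _PatchScanner(channels, valid, side, window)

    unsolved = fill_set.copy()
    alpha = params.alpha
    log: list[FillRecord] = []
    for pass_number in range(1, params.max_passes + 1):
        if not unsolved.any():
            break
        schedule = processing_schedule(unsolved, unsolved | prior_invalid)
        solved_this_pass = 0
        for p in schedule:
            p = tuple(int(v) for v in p)
            match = scanner.best_match(p, admissible, alpha, params.c)
            if not match.satisfied_constraint:
                continue
            q = match.q_hat
            src = scanner.channels[:, q[0] + scanner.h, q[1] + scanner.h,
                                   q[2] + scanner.h]
            lesioned = lesions[:, p[0], p[1], p[2]]
            tgt = scanner.channels[:, p[0] + scanner.h, p[1] + scanner.h,
                                   p[2] + scanner.h]
            tgt[lesioned] = src[lesioned]
            scanner.set_valid(p, True)
            unsolved[p] = False
            solved_this_pass += 1
            log.append(FillRecord(p, q, match.distance, match.kappa, pass_number))
        if solved_this_pass == 0 and unsolved.any():
            alpha *= params.alpha_relax_factor
            logger.warning(
                "pass %d solved no voxels; relaxing alpha to %.4g "
                "(%d voxels remain)", pass_number, alpha, int(unsolved.sum()))
    if unsolved.any():
        raise RuntimeError(
            f"max_passes={params.max_passes} exhausted with "
            f"{int(unsolved.sum())} unsolved voxels")

    h = scanner.h
    filled = scanner.channels[:, h:h + volume.spatial_shape[0],
                              h:h + volume.spatial_shape[1],
                              h:h + volume.spatial_shape[2]]
    out = Volume5D.from_channels(filled.copy(), volume.n_modalities,
                                 volume.n_timepoints, volume.voxel_to_world)
    return out, log


def apply_buffing(filled: Volume5D, maskset: ChannelMaskSet,
                  kernel: np.ndarray) -> Volume5D:
    """Smooth the filled region with the buffing kernel, per channel.

    Only originally-lesioned voxels are replaced; neighbour values are read
    from the (pre-buffing) filled image, out-of-bounds neighbours are dropped
    and the kernel renormalised at the borders.
    """
    channels = filled.channels().astype(np.float64)
    lesions = maskset.channel_lesions()
    norm = ndimage.convolve(np.ones(filled.spatial_shape), kernel,
                            mode="constant", cval=0.0)
    out = channels.copy()
    for c in range(channels.shape[0]):
        if not lesions[c].any():
            continue
        conv = ndimage.convolve(channels[c], kernel, mode="constant", cval=0.0)
        buffed = conv / norm
        out[c][lesions[c]] = buffed[lesions[c]]
    return Volume5D.from_channels(out, filled.n_modalities, filled.n_timepoints,
                                  filled.voxel_to_world)


def write_fill_log(log: list[FillRecord], path) -> None:
    """Emit the fill log as TSV: p_x p_y p_z q_x q_y q_z D kappa pass."""
    with open(path, "w") as fh:
        fh.write("p_x\tp_y\tp_z\tq_x\tq_y\tq_z\tD\tkappa\tpass\n")
        for rec in log:
            fh.write("\t".join(map(str, (*rec.p, *rec.q, rec.distance,
                                         rec.kappa, rec.pass_number))) + "\n")
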