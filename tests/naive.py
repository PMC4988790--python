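"""Independent reference implementations used as test oracles.

These re-derive the method's quantities by the most literal route available
— KD-tree nearest-neighbour search for distance maps, explicit per-candidate
loops for the patch scan — deliberately sharing no code with the optimised
implementation they check.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def brute_distance_map(excluded: np.ndarray) -> np.ndarray:
    """Distance from each in-set voxel to the nearest out-of-set voxel,
    via explicit nearest-neighbour search over all outside voxels."""
    excluded = np.asarray(excluded, bool)
    out = np.zeros(excluded.shape)
    outside = np.argwhere(~excluded)
    inside = np.argwhere(excluded)
    if len(inside) == 0:
        return out
    tree = cKDTree(outside)
    d, _ = tree.query(inside)
    out[tuple(inside.T)] = d
    return out


def _odd_up(v: float) -> int:
    s = int(np.ceil(v))
    if s % 2 == 0:
        s += 1
    return max(s, 3)


def naive_inpaint(channels, lesions, prior_valid=None, alpha=0.5, c=2.0,
                  window_multiplier=4, patch_side=None, max_passes=100,
                  relax=0.5):
    """Literal multi-pass concentric patch fill.

    ``channels``: (C, X, Y, Z) float stack; ``lesions``: matching boolean
    stack.  Returns ``(filled_channels, log)`` with log entries
    (p, q, D, kappa, pass_number).
    """
    channels = np.array(channels, dtype=float)
    lesions = np.asarray(lesions, bool)
    shape = channels.shape[1:]
    fill_set = lesions.any(axis=0)
    prior_invalid = (~np.asarray(prior_valid, bool) if prior_valid is not None
                     else np.zeros(shape, bool))
    excluded = fill_set | prior_invalid

    dist0 = brute_distance_map(excluded)
    if patch_side is None:
        w = _odd_up(dist0[fill_set].max() + 1.0)
    else:
        w = patch_side
    W = window_multiplier * w
    if W % 2 == 0:
        W += 1
    hw, hW = w // 2, W // 2
    offsets = [(dx, dy, dz)
               for dz in range(-hw, hw + 1)
               for dy in range(-hw, hw + 1)
               for dx in range(-hw, hw + 1)]
    n_total = channels.shape[0] * w ** 3

    valid = ~lesions
    unsolved = fill_set.copy()
    log = []

    def patch_values(centre):
        """(C, w^3) values and validity at centre, out-of-bounds invalid."""
        vals = np.zeros((channels.shape[0], len(offsets)))
        ok = np.zeros((channels.shape[0], len(offsets)), bool)
        for k, (dx, dy, dz) in enumerate(offsets):
            x, y, z = centre[0] + dx, centre[1] + dy, centre[2] + dz
            if 0 <= x < shape[0] and 0 <= y < shape[1] and 0 <= z < shape[2]:
                vals[:, k] = channels[:, x, y, z]
                ok[:, k] = valid[:, x, y, z]
        return vals, ok

    a = alpha
    for pass_number in range(1, max_passes + 1):
        if not unsolved.any():
            break
        dist = brute_distance_map(unsolved | prior_invalid)
        targets = sorted(map(tuple, np.argwhere(unsolved)),
                         key=lambda p: (dist[p], p[2], p[1], p[0]))
        solved = 0
        for p in targets:
            tvals, tok = patch_values(p)
            best = None
            for qz in range(max(0, p[2] - hW), min(shape[2], p[2] + hW + 1)):
                for qy in range(max(0, p[1] - hW), min(shape[1], p[1] + hW + 1)):
                    for qx in range(max(0, p[0] - hW), min(shape[0], p[0] + hW + 1)):
                        q = (qx, qy, qz)
                        if q == p or excluded[q]:
                            continue
                        svals, sok = patch_values(q)
                        joint = tok & sok
                        kappa = int(joint.sum())
                        if kappa <= a * n_total:
                            continue
                        d = ((tvals - svals) ** 2 * joint).sum() / kappa ** c
                        if best is None or d < best[0]:
                            best = (d, kappa, q)
            if best is None:
                continue
            d, kappa, q = best
            sel = lesions[:, p[0], p[1], p[2]]
            channels[sel, p[0], p[1], p[2]] = channels[sel, q[0], q[1], q[2]]
            valid[:, p[0], p[1], p[2]] = True
            unsolved[p] = False
            solved += 1
            log.append((p, q, d, kappa, pass_number))
        if solved == 0 and unsolved.any():
            a *= relax
    if unsolved.any():
        raise RuntimeError("naive fill did not converge")
    return channels, log
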