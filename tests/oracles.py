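"""Independent brute-force oracles used to pin down expected values.

These deliberately share no code with the package implementations: local
thickness is computed by enumerating every candidate sphere center and
radius, and precision/recall by direct pixel-pair counting.
"""

import numpy as np


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Maximal-inscribed-sphere thickness by exhaustive enumeration.

    A sphere of integer radius r at center c covers voxels u with
    ||u - c||^2 <= r^2 and must lie entirely inside the grid and the phase;
    thickness(v) = max 2r+1 over all spheres covering v.  O(n * r^3): only
    for grids up to ~20^3.
    """
    mask = np.asarray(mask, dtype=bool)
    shape = np.array(mask.shape)
    out = np.zeros(mask.shape, dtype=np.float32)

    def ball_offsets(r):
        g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
        keep = (g**2).sum(axis=0) <= r * r
        return g[:, keep].T  # (k, 3)

    offsets_cache = {}
    for c in np.argwhere(mask):
        r = 0
        while True:
            rn = r + 1
            if (c - rn < 0).any() or (c + rn >= shape).any():
                break  # sphere would leave the grid: phase ends at the border
            offs = offsets_cache.setdefault(rn, ball_offsets(rn))
            pts = c + offs
            if mask[pts[:, 0], pts[:, 1], pts[:, 2]].all():
                r = rn
            else:
                break
        offs = offsets_cache.setdefault(r, ball_offsets(r))
        pts = c + offs
        d = 2 * r + 1
        vals = out[pts[:, 0], pts[:, 1], pts[:, 2]]
        out[pts[:, 0], pts[:, 1], pts[:, 2]] = np.maximum(vals, d)
    return out


def counting_precision_recall(true: np.ndarray, pred: np.ndarray, codes) -> dict:
    """Per-class precision/recall by direct counting over pixel pairs."""
    true, pred = np.asarray(true).ravel(), np.asarray(pred).ravel()
    out = {}
    for k in codes:
        tp = int(((true == k) & (pred == k)).sum())
        fn = int(((true == k) & (pred != k)).sum())
        fp = int(((true != k) & (pred == k)).sum())
        out[k] = {
            "recall": tp / (tp + fn) if tp + fn else np.nan,
            "precision": tp / (tp + fp) if tp + fp else np.nan,
        }
    return out
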