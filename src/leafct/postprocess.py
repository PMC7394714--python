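"""Anatomy-aware corrections applied to a raw predicted label stack.

Two rules from leaf anatomy: (1) each epidermis (adaxial and abaxial) must
form a single connected volume, so only the two largest epidermis components
of similar volume are kept and re-assigned to sides by position, all other
epidermis voxels being false positives inside the mesophyll; (2) veins and
bundle sheaths are continuous structures, so tiny isolated components
(below 27 voxels by default) are noise and are removed.  Corrections only
relabel voxels — the total voxel count is conserved — and are idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .stack_io import LabelStack

logger = logging.getLogger(__name__)

#: flag set on a stack whose epidermes could not be told apart
EPIDERMES_CONNECTED = "epidermes_connected"


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def catalog_components(labels: LabelStack, classes, connectivity: int = 26) -> pd.DataFrame:
    """3D connected-component catalog per class.

    Returns one row per component with class name/code, component id, voxel
    count, centroid (z, y, x) and bounding box (half-open index ranges).
    """
    classes = list(classes)
    if not classes:
        raise ValueError("classes must be nonempty")
    struct = _structure(connectivity)
    rows = []
    for name in classes:
        code = labels.class_map.code(name)
        mask = labels.voxels == code
        lab, n = ndimage.label(mask, structure=struct)
        if n == 0:
            continue
        ids = np.arange(1, n + 1)
        counts = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab, ids)
        centroids = ndimage.center_of_mass(mask, lab, ids)
        boxes = ndimage.find_objects(lab)
        for cid, cnt, cen, box in zip(ids, counts, centroids, boxes):
            rows.append(
                {
                    "class_name": name,
                    "class_code": code,
                    "component_id": int(cid),
                    "voxel_count": int(cnt),
                    "centroid_z": cen[0],
                    "centroid_y": cen[1],
                    "centroid_x": cen[2],
                    "bbox": tuple((s.start, s.stop) for s in box),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "class_name",
            "class_code",
            "component_id",
            "voxel_count",
            "centroid_z",
            "centroid_y",
            "centroid_x",
            "bbox",
        ],
    )


def correct_epidermis(
    labels: LabelStack,
    similarity_ratio: float = 5.0,
    connectivity: int = 26,
    adaxial_is_low_row: bool = True,
) -> LabelStack:
    """Keep the two largest similar-volume epidermis components; drop the rest.

    All voxels predicted as either epidermis class are pooled, connected
    components are ranked by volume, and the two largest are kept provided
    their volume ratio (larger/smaller) does not exceed ``similarity_ratio``.
    Kept components are assigned adaxial/abaxial by mean row position (lower
    mean row = adaxial by default, i.e. the image top faces up).  Every other
    epidermis voxel is reassigned to mesophyll cell.  If the epidermes are
    merged into one component, or the two largest are too dissimilar — the
    typical 1-2-training-slice failure — the stack is returned unchanged with
    the ``epidermes_connected`` flag set so side-specific traits are withheld.
    """
    cm = labels.class_map
    code_ad, code_ab = cm.code("epidermis_adaxial"), cm.code("epidermis_abaxial")
    code_cell = cm.code("mesophyll_cell")
    mask = (labels.voxels == code_ad) | (labels.voxels == code_ab)
    if not mask.any():
        raise ValueError("no epidermis voxels in stack")
    lab, n = ndimage.label(mask, structure=_structure(connectivity))
    counts = np.bincount(lab.ravel())[1:]  # component id i -> counts[i-1]
    order = np.argsort(counts)[::-1]
    flagged = False
    if n < 2:
        flagged = True
    else:
        big, second = counts[order[0]], counts[order[1]]
        if big / second > similarity_ratio:
            flagged = True
    if flagged:
        logger.warning("epidermes connected or indistinct: correction withheld")
        out = replace(labels, voxels=labels.voxels.copy(), flags=set(labels.flags))
        out.flags.add(EPIDERMES_CONNECTED)
        return out

    keep_ids = [int(order[0]) + 1, int(order[1]) + 1]
    mean_rows = [ndimage.center_of_mass(lab == i)[1] for i in keep_ids]
    if (mean_rows[0] > mean_rows[1]) == adaxial_is_low_row:
        keep_ids = keep_ids[::-1]  # first entry = adaxial
    vox = labels.voxels.copy()
    vox[mask] = code_cell
    vox[lab == keep_ids[0]] = code_ad
    vox[lab == keep_ids[1]] = code_ab
    n_removed = int(mask.sum() - counts[order[0]] - counts[order[1]])
    if n_removed:
        logger.info("epidermis correction: %d speckle voxels -> mesophyll_cell", n_removed)
    return replace(labels, voxels=vox, flags=set(labels.flags))


def filter_small_components(
    labels: LabelStack,
    classes=("vein", "bundle_sheath"),
    min_voxels: int = 27,
    connectivity: int = 26,
) -> LabelStack:
    """Reassign components smaller than ``min_voxels`` to mesophyll cell.

    The default threshold of 27 voxels (a 3x3x3 cube) matches the scale below
    which an isolated vein/bundle-sheath volume cannot be real tissue; a
    component of exactly ``min_voxels`` survives (the rule is strictly
    "below").
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    cm = labels.class_map
    code_cell = cm.code("mesophyll_cell")
    vox = labels.voxels.copy()
    struct = _structure(connectivity)
    for name in classes:
        code = cm.code(name)
        mask = labels.voxels == code
        if not mask.any():
            continue
        lab, n = ndimage.label(mask, structure=struct)
        counts = np.bincount(lab.ravel())
        small = np.nonzero(counts[1:] < min_voxels)[0] + 1
        if small.size:
            vox[np.isin(lab, small)] = code_cell
            logger.info(
                "%s: removed %d components < %d voxels (sizes %s)",
                name,
                small.size,
                min_voxels,
                sorted(int(counts[i]) for i in small),
            )
    return replace(labels, voxels=vox, flags=set(labels.flags))


def apply_corrections(
    labels: LabelStack,
    similarity_ratio: float = 5.0,
    min_voxels: int = 27,
    connectivity: int = 26,
) -> LabelStack:
    """Standard correction sequence: epidermis rule, then small-volume rule."""
    out = correct_epidermis(labels, similarity_ratio, connectivity)
    return filter_small_components(out, min_voxels=min_voxels, connectivity=connectivity)
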