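"""Per-pixel feature-layer engineering for slice-wise classification.

Each 2D slice of the paired reconstructions is expanded into a stack of
feature layers: multi-scale Gaussian blurs and square-window variance filters
of the raw gridrec and phase-contrast images, of their Sobel gradient
magnitudes, and of a top/bottom edge-distance map, plus the raw intensities
and the slice of the 3D local-thickness map.  Features are strictly 2D per
slice (the local-thickness layer carries the only 3D context), borders are
handled by reflection, and values are stored as float32 without rescaling
(tree ensembles are scale-invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Scales and switches for the feature-layer recipe.

    Defaults span a geometric ladder from cell-wall to vein scale at the
    half-resolution pixel size (0.325 um/px) of a typical 40x synchrotron
    scan.  ``fast()`` is a compact ladder for small volumes where the largest
    scales exceed the image extent.
    """

    gaussian_sigmas: tuple[float, ...] = (2, 4, 8, 16, 32, 64)
    variance_windows: tuple[int, ...] = (3, 9, 17)
    include_sobel: bool = True
    include_edge_distance: bool = True
    include_local_thickness: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "gaussian_sigmas", tuple(float(s) for s in self.gaussian_sigmas))
        object.__setattr__(self, "variance_windows", tuple(int(w) for w in self.variance_windows))
        if not self.gaussian_sigmas and not self.variance_windows:
            raise ValueError("at least one filter scale is required")
        if any(s <= 0 for s in self.gaussian_sigmas) or any(w <= 0 for w in self.variance_windows):
            raise ValueError("all filter scales must be positive")

    @classmethod
    def fast(cls) -> "FeatureConfig":
        return cls(gaussian_sigmas=(2, 4, 8, 16), variance_windows=(3, 9))

    def column_names(self) -> list[str]:
        bases = ["gridrec", "phase"]
        if self.include_sobel:
            bases += ["sobel_gridrec", "sobel_phase"]
        if self.include_edge_distance:
            bases.append("edge_distance")
        cols = []
        for b in bases:
            cols += [f"{b}_gauss{g:g}" for g in self.gaussian_sigmas]
            cols += [f"{b}_var{w}" for w in self.variance_windows]
        cols += ["gridrec_raw", "phase_raw"]
        if self.include_local_thickness:
            cols.append("local_thickness")
        return cols


@dataclass
class FeatureTable:
    """Per-pixel feature matrix: one row per pixel, one column per layer."""

    values: np.ndarray  # (n_pixels, n_layers) float32
    columns: list[str]
    target: np.ndarray | None = None  # class code per row (training only)
    origin: np.ndarray | None = None  # (n_pixels, 3) int (z, y, x) per row

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("feature matrix shape inconsistent with column names")
        if self.target is not None and len(self.target) != len(self.values):
            raise ValueError("target length != row count")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def edge_distance_map(shape: tuple[int, int]) -> np.ndarray:
    """Pixel distance to the nearer of the top and bottom image edges.

    Column-independent; increases toward the vertical center of the image.
    """
    rows, cols = shape
    if rows < 1 or cols < 1:
        raise ValueError(f"invalid image shape {shape}")
    r = np.arange(rows, dtype=np.float32)
    profile = np.minimum(r, rows - 1 - r)
    return np.repeat(profile[:, None], cols, axis=1)


def _variance_filter(img: np.ndarray, window: int) -> np.ndarray:
    mean = ndimage.uniform_filter(img, window, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, window, mode="reflect")
    return np.maximum(mean_sq - mean * mean, 0.0)


def _sobel_magnitude(img: np.ndarray) -> np.ndarray:
    gy = ndimage.sobel(img, axis=0, mode="reflect")
    gx = ndimage.sobel(img, axis=1, mode="reflect")
    return np.hypot(gy, gx)


def build_features(
    gridrec_slice: np.ndarray,
    phase_slice: np.ndarray,
    lt_slice: np.ndarray | None,
    cfg: FeatureConfig,
) -> FeatureTable:
    """Build the feature table for one slice; rows in row-major pixel order."""
    g = np.asarray(gridrec_slice, dtype=np.float32)
    p = np.asarray(phase_slice, dtype=np.float32)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gridrec {g.shape} vs phase {p.shape}")
    if cfg.include_local_thickness:
        if lt_slice is None:
            raise ValueError("configuration includes local thickness but no map was given")
        lt = np.asarray(lt_slice, dtype=np.float32)
        if lt.shape != g.shape:
            raise ValueError(f"shape mismatch: local thickness {lt.shape} vs slice {g.shape}")

    bases = [g, p]
    if cfg.include_sobel:
        bases += [_sobel_magnitude(g), _sobel_magnitude(p)]
    if cfg.include_edge_distance:
        bases.append(edge_distance_map(g.shape))

    layers: list[np.ndarray] = []
    for img in bases:
        for s in cfg.gaussian_sigmas:
            layers.append(ndimage.gaussian_filter(img, s, mode="reflect"))
        for w in cfg.variance_windows:
            layers.append(_variance_filter(img, w))
    layers += [g, p]
    if cfg.include_local_thickness:
        layers.append(lt)

    values = np.stack([l.astype(np.float32).ravel() for l in layers], axis=1)
    return FeatureTable(values, cfg.column_names())


def assemble_training_table(
    gridrec,
    phase,
    lt_map,
    labels,
    slice_indices: Sequence[int],
    cfg: FeatureConfig,
) -> FeatureTable:
    """Concatenate labeled-slice feature tables with class targets.

    Rows carrying the unlabeled sentinel are dropped; row order is
    deterministic (slice order given, then row-major pixel order).
    """
    slice_indices = [int(z) for z in slice_indices]
    if not slice_indices:
        raise ValueError("no training slices given")
    labeled = set(labels.labeled_slice_indices or range(labels.shape[0]))
    missing = [z for z in slice_indices if z not in labeled]
    if missing:
        raise ValueError(f"slices {missing} carry no hand labels")

    sentinel = labels.class_map.sentinel
    vals, targs, origins = [], [], []
    for z in slice_indices:
        lt_slice = lt_map.voxels[z] if cfg.include_local_thickness else None
        tab = build_features(gridrec.voxels[z], phase.voxels[z], lt_slice, cfg)
        target = labels.voxels[z].ravel()
        keep = target != sentinel
        yy, xx = np.unravel_index(np.nonzero(keep)[0], labels.shape[1:])
        vals.append(tab.values[keep])
        targs.append(target[keep].astype(np.int64))
        origins.append(np.column_stack([np.full(yy.size, z), yy, xx]))

    values = np.concatenate(vals, axis=0)
    target = np.concatenate(targs)
    origin = np.concatenate(origins, axis=0)
    if values.shape[0] == 0:
        raise ValueError("empty training table: no labeled pixels on the given slices")
    if np.unique(target).size < 2:
        logger.warning("degenerate training set: a single class on the selected slices")
    return FeatureTable(values, cfg.column_names(), target=target, origin=origin)
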