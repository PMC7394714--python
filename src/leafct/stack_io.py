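"""Stack input/output, tissue class bookkeeping and voxel geometry.

All 3D arrays in this package use axis order ``(z, y, x)`` where ``z`` is the
slice index, ``y`` the image row (the adaxial-abaxial leaf axis for an upright
mount) and ``x`` the image column.  Indices are 0-based, ranges half-open.
Voxel edge lengths are given per axis in micrometres as ``(z, y, x)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: canonical tissue names, in default code order
TISSUE_NAMES = (
    "background",
    "epidermis_adaxial",
    "epidermis_abaxial",
    "mesophyll_cell",
    "airspace",
    "vein",
    "bundle_sheath",
)

Spacing = tuple[float, float, float]


def _validate_spacing(spacing: Sequence[float]) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 strictly positive values (z, y, x), got {spacing}")
    return spacing


@dataclass(frozen=True)
class ClassMap:
    """Mapping from tissue name to a distinct non-negative integer code.

    The reserved *unlabeled sentinel* (``max(code) + 1``) marks voxels of a
    sparse hand-labeled stack that carry no ground truth; it is never a member
    of the map and never enters training.
    """

    codes: Mapping[str, int]

    def __post_init__(self) -> None:
        codes = dict(self.codes)
        object.__setattr__(self, "codes", codes)
        if "background" not in codes:
            raise ValueError("class map must contain 'background'")
        vals = list(codes.values())
        if any((not isinstance(v, (int, np.integer))) or v < 0 for v in vals):
            raise ValueError("class codes must be non-negative integers")
        if len(set(vals)) != len(vals):
            raise ValueError("class codes must be unique")

    @classmethod
    def default(cls) -> "ClassMap":
        return cls({name: i for i, name in enumerate(TISSUE_NAMES)})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.codes)

    @property
    def sentinel(self) -> int:
        """Reserved code for unlabeled voxels in sparse label stacks."""
        return max(self.codes.values()) + 1

    def code(self, name: str) -> int:
        try:
            return self.codes[name]
        except KeyError:
            raise KeyError(f"unknown tissue class {name!r}; known: {sorted(self.codes)}") from None

    def name(self, code: int) -> str:
        for n, c in self.codes.items():
            if c == int(code):
                return n
        raise KeyError(f"code {code} not in class map")

    def __contains__(self, name: str) -> bool:
        return name in self.codes


@dataclass
class ReconstructionStack:
    """8-bit grayscale microCT reconstruction volume."""

    voxels: np.ndarray  # (z, y, x) uint8
    spacing: Spacing
    modality: str  # "gridrec" or "phase"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {self.voxels.shape}")
        if self.voxels.dtype != np.uint8:
            raise ValueError(f"unsupported bit depth: expected 8-bit, got {self.voxels.dtype}")
        self.spacing = _validate_spacing(self.spacing)
        if self.modality not in ("gridrec", "phase"):
            raise ValueError(f"modality must be 'gridrec' or 'phase', got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelStack:
    """3D grid of integer tissue-class codes sharing geometry with its scan.

    For sparse hand-labeled stacks, ``labeled_slice_indices`` lists the z
    positions that carry ground truth; every other slice is filled with the
    class map's sentinel code.
    """

    voxels: np.ndarray  # (z, y, x) integer codes
    class_map: ClassMap
    spacing: Spacing
    labeled_slice_indices: tuple[int, ...] | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D label stack, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("label voxels must be integer class codes")
        self.spacing = _validate_spacing(self.spacing)
        if self.labeled_slice_indices is not None:
            self.labeled_slice_indices = tuple(int(i) for i in self.labeled_slice_indices)
        allowed = set(self.class_map.codes.values()) | {self.class_map.sentinel}
        check = (
            self.voxels
            if self.labeled_slice_indices is None
            else self.voxels[list(self.labeled_slice_indices)]
        )
        present = set(np.unique(check).tolist())
        if self.labeled_slice_indices is not None:
            present |= set(np.unique(self.voxels).tolist())
        unknown = present - allowed
        if unknown:
            raise ValueError(f"label codes {sorted(unknown)} absent from class map")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def is_sparse(self) -> bool:
        return self.labeled_slice_indices is not None

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels belonging to any of the named classes."""
        out = np.zeros(self.shape, dtype=bool)
        for n in names:
            out |= self.voxels == self.class_map.code(n)
        return out


# ---------------------------------------------------------------------------
# reading / writing


def _read_tiff_volume(path: Path) -> np.ndarray:
    """Read a multi-page TIFF or a directory of per-slice TIFFs as (z, y, x)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        pages = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not pages:
            raise FileNotFoundError(f"no TIFF/PNG slices found in directory {path}")
        slices = []
        for p in pages:
            from imageio.v3 import imread  # PNG label slices

            arr = imread(p) if p.suffix.lower() == ".png" else tifffile.imread(p)
            if arr.ndim != 2:
                raise ValueError(f"slice {p} is not single-channel 2D (shape {arr.shape})")
            slices.append(arr)
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice dimensions in {path}: {sorted(shapes)}")
        return np.stack(slices, axis=0)
    vol = tifffile.imread(path)
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError(f"expected 2D/3D TIFF, got shape {vol.shape}")
    return vol


def read_stack(path: str | Path, spacing: Sequence[float], modality: str) -> ReconstructionStack:
    """Read an 8-bit grayscale reconstruction from a multi-page TIFF.

    16-bit (or any non-8-bit) input is rejected rather than silently rescaled.
    """
    vol = _read_tiff_volume(Path(path))
    if vol.dtype != np.uint8:
        raise ValueError(f"unsupported bit depth: {vol.dtype} (expected 8-bit); convert upstream")
    return ReconstructionStack(vol, _validate_spacing(spacing), modality)


def write_stack(path: str | Path, stack: ReconstructionStack) -> None:
    tifffile.imwrite(Path(path), stack.voxels, photometric="minisblack")


def read_labels(
    path: str | Path,
    class_map: ClassMap,
    slice_indices: Sequence[int],
    full_shape: tuple[int, int, int],
    spacing: Sequence[float],
) -> LabelStack:
    """Read sparse hand-labeled slices into a sentinel-padded LabelStack.

    ``path`` holds one single-channel integer image per labeled slice (a
    multi-page TIFF or a directory), in the same order as ``slice_indices``,
    which give each image's z position in the full stack of ``full_shape``.
    """
    slice_indices = [int(i) for i in slice_indices]
    if not slice_indices:
        raise ValueError("no training labels: slice_indices is empty")
    nz = full_shape[0]
    bad = [i for i in slice_indices if not 0 <= i < nz]
    if bad:
        raise IndexError(f"slice indices {bad} out of range for {nz}-slice stack")
    imgs = _read_tiff_volume(Path(path))
    if imgs.shape[0] != len(slice_indices):
        raise ValueError(f"{imgs.shape[0]} label images but {len(slice_indices)} slice indices")
    if imgs.shape[1:] != tuple(full_shape[1:]):
        raise ValueError(f"label image shape {imgs.shape[1:]} != stack slice shape {full_shape[1:]}")
    known = set(class_map.codes.values())
    present = set(np.unique(imgs).tolist())
    unknown = present - known
    if unknown:
        raise ValueError(f"label codes {sorted(unknown)} absent from class map")
    sentinel = class_map.sentinel
    vox = np.full(full_shape, sentinel, dtype=np.min_scalar_type(sentinel))
    for img, z in zip(imgs, slice_indices):
        vox[z] = img
    return LabelStack(vox, class_map, _validate_spacing(spacing), tuple(slice_indices))


def write_labels(path: str | Path, labels: LabelStack) -> None:
    """Write a LabelStack as an 8-bit multi-page TIFF of class codes."""
    vox = labels.voxels
    if vox.max(initial=0) > 255:
        raise ValueError("class codes exceed 8-bit range")
    tifffile.imwrite(Path(path), vox.astype(np.uint8), photometric="minisblack")


# ---------------------------------------------------------------------------
# downsampling


def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    z, y, x = a.shape
    yc, xc = (y // factor) * factor, (x // factor) * factor
    if (yc, xc) != (y, x):
        logger.info("downsample_xy: cropping trailing rows/cols %s -> %s", (y, x), (yc, xc))
    a = a[:, :yc, :xc]
    return a.reshape(z, yc // factor, factor, xc // factor, factor)


def downsample_xy(stack, factor: int):
    """Downsample the x and y axes by an integer factor; z is untouched.

    Grayscale stacks use block averaging (rounded half-to-even back to 8-bit);
    label stacks use the block mode with ties broken toward the smallest code.
    The y and x voxel spacings are multiplied by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsampling factor must be >= 1, got {factor}")
    if factor == 1:
        return replace(stack, voxels=stack.voxels.copy())
    sz, sy, sx = stack.spacing
    new_spacing = (sz, sy * factor, sx * factor)
    if isinstance(stack, ReconstructionStack):
        blocks = _block_view(stack.voxels.astype(np.float64), factor)
        means = blocks.mean(axis=(2, 4))
        vox = np.rint(means).astype(np.uint8)  # rint rounds half to even
        return ReconstructionStack(vox, new_spacing, stack.modality)
    if isinstance(stack, LabelStack):
        blocks = _block_view(stack.voxels, factor)
        codes = np.unique(stack.voxels)  # ascending: argmax tie -> smallest code
        counts = np.stack([(blocks == c).sum(axis=(2, 4)) for c in codes], axis=0)
        vox = codes[np.argmax(counts, axis=0)].astype(stack.voxels.dtype)
        return LabelStack(
            vox, stack.class_map, new_spacing, stack.labeled_slice_indices, set(stack.flags)
        )
    raise TypeError(f"cannot downsample object of type {type(stack).__name__}")
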