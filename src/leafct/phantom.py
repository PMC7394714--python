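"""Synthetic microCT-like leaf phantom with voxel-exact ground truth.

The phantom is a laminar leaf slab in air: two continuous epidermis layers,
a mesophyll of cells with an interconnected airspace carved from seeded
spherical voids, and z-running cylindrical veins wrapped by bundle-sheath
rings.  Two noisy grayscale modalities are rendered with class-dependent
mean intensities — the phase-contrast-like modality with a larger cell/air
contrast than the absorption-like one — alongside the exact truth labels.

Realism notes: void density increases linearly toward the abaxial (lower)
side, mimicking the spongy/palisade asymmetry of real laminas (and giving
context features something to tell the two otherwise identically rendered
epidermis layers apart, as in real scans); background outside the leaf and
internal airspace share the same mean intensity, as they are the same
material in a real scan.  Reconstruction physics (ring artifacts, phase
fringes) is not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .stack_io import ClassMap, LabelStack, ReconstructionStack, Spacing

#: per-class mean intensities, well separated ("easy", the default)
EASY_INTENSITIES = {
    "gridrec": {
        "background": 35, "airspace": 35, "mesophyll_cell": 140,
        "epidermis_adaxial": 170, "epidermis_abaxial": 170,
        "vein": 200, "bundle_sheath": 110,
    },
    "phase": {
        "background": 20, "airspace": 20, "mesophyll_cell": 170,
        "epidermis_adaxial": 210, "epidermis_abaxial": 210,
        "vein": 240, "bundle_sheath": 140,
    },
}

#: near-coincident tissue intensities ("hard"): cells, epidermis, veins and
#: sheaths are all water-filled tissue with almost no grayscale contrast, as
#: in real scans — only structural/positional context can separate them
HARD_INTENSITIES = {
    "gridrec": {
        "background": 40, "airspace": 40, "mesophyll_cell": 130,
        "epidermis_adaxial": 134, "epidermis_abaxial": 134,
        "vein": 138, "bundle_sheath": 126,
    },
    "phase": {
        "background": 30, "airspace": 30, "mesophyll_cell": 150,
        "epidermis_adaxial": 155, "epidermis_abaxial": 155,
        "vein": 160, "bundle_sheath": 145,
    },
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise of a synthetic leaf scan.

    Defaults approximate a half-resolution grapevine-leaf scan: 0.325 um
    pixels in (y, x), 0.1625 um slices, a ~60-um lamina (two 12-voxel
    epidermis layers around a 160-voxel mesophyll), 35% mesophyll porosity
    and three 10-voxel-radius veins with 4-voxel bundle-sheath rings.
    """

    shape: tuple[int, int, int] = (200, 256, 256)
    spacing: Spacing = (0.1625, 0.325, 0.325)
    epidermis_thickness: int = 12  # voxels per side
    mesophyll_thickness: int = 160  # voxels
    target_porosity: float = 0.35
    void_radius_range: tuple[int, int] = (4, 12)
    vein_count: int = 3
    vein_radius: int = 10
    sheath_thickness: int = 4
    undulation_amplitude: tuple[float, float] = (8.0, 4.0)  # voxels, (along z, along x)
    intensities: dict = field(default_factory=lambda: EASY_INTENSITIES)
    noise_sd: float = 8.0
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        z, y, x = self.shape
        leaf = 2 * self.epidermis_thickness + self.mesophyll_thickness
        if leaf > y:
            raise ValueError(f"leaf thickness {leaf} voxels exceeds y extent {y}")
        margin = (y - leaf) // 2
        if margin < sum(self.undulation_amplitude) + 1:
            raise ValueError(
                f"undulation amplitude {self.undulation_amplitude} does not fit the "
                f"{margin}-voxel background margin"
            )
        if not 0 < self.target_porosity < 1:
            raise ValueError("target porosity must be in (0, 1)")
        for mod in ("gridrec", "phase"):
            for v in self.intensities[mod].values():
                if not 0 <= v <= 255:
                    raise ValueError("class intensities must be within [0, 255]")
        if self.vein_count:
            pitch = x / (self.vein_count + 1)
            if 2 * (self.vein_radius + self.sheath_thickness) >= pitch:
                raise ValueError("veins overlap: reduce count or radius")

    @classmethod
    def easy(cls, **kw) -> "PhantomSpec":
        return cls(intensities=EASY_INTENSITIES, **kw)

    @classmethod
    def hard(cls, **kw) -> "PhantomSpec":
        return cls(intensities=HARD_INTENSITIES, noise_sd=10.0, **kw)

    @property
    def leaf_thickness_voxels(self) -> int:
        return 2 * self.epidermis_thickness + self.mesophyll_thickness


@dataclass
class PhantomBundle:
    """Rendered modalities + truth labels + analytic trait expectations."""

    gridrec: ReconstructionStack
    phase: ReconstructionStack
    truth: LabelStack
    spec: PhantomSpec
    expected_traits: dict


def _lamina_offsets(spec: PhantomSpec) -> np.ndarray:
    """Integer vertical offset of the lamina per (z, x) column.

    A gentle sinusoidal bow along the stack depth plus a transverse ripple:
    real laminas are never perfectly flat, and the resulting slice-to-slice
    variation is what makes a single training slice unrepresentative of the
    rest of the scan.  Integer offsets shift whole columns, so per-column
    thickness closed forms remain exact.
    """
    z_ext, _, x_ext = spec.shape
    a_z, a_x = spec.undulation_amplitude
    oz = a_z * np.sin(2 * np.pi * np.arange(z_ext) / z_ext)
    ox = a_x * np.sin(2 * np.pi * np.arange(x_ext) / x_ext + 1.0)
    return np.rint(oz[:, None] + ox[None, :]).astype(np.int64)  # (z, x)


def _carve_airspace(
    truth: np.ndarray, cm: ClassMap, spec: PhantomSpec, offsets: np.ndarray, rng
) -> None:
    """Grow spherical voids (cell -> airspace) until porosity hits target.

    Void centers are sampled with a linear density gradient toward the
    abaxial side (spongy mesophyll below, denser palisade-like tissue
    adaxially); only mesophyll-cell voxels are carved, so veins, sheaths and
    epidermes stay intact.  Stops within +/-0.02 of the target (each void is
    tiny relative to the mesophyll, so no overshoot control needed).
    """
    z_ext, y_ext, x_ext = truth.shape
    e, m = spec.epidermis_thickness, spec.mesophyll_thickness
    y0 = (y_ext - spec.leaf_thickness_voxels) // 2
    cell_code, air_code = cm.code("mesophyll_cell"), cm.code("airspace")
    meso_codes = [cell_code, air_code, cm.code("vein"), cm.code("bundle_sheath")]

    meso_total = int(np.isin(truth, meso_codes).sum())
    rmin, rmax = spec.void_radius_range
    air_count = 0
    target_count = spec.target_porosity * meso_total
    while air_count < target_count:
        r = int(rng.integers(rmin, rmax + 1))
        cz = int(rng.integers(0, z_ext))
        cx = int(rng.integers(0, x_ext))
        # abaxial bias: quadratic inverse-cdf => linear density ramp along y
        meso_lo = y0 + e + int(offsets[cz, cx])
        cy = int(meso_lo + (m - 1) * np.sqrt(rng.random()))
        zlo, zhi = max(cz - r, 0), min(cz + r + 1, z_ext)
        ylo, yhi = max(cy - r, 0), min(cy + r + 1, y_ext)
        xlo, xhi = max(cx - r, 0), min(cx + r + 1, x_ext)
        zz, yy, xx = np.ogrid[zlo:zhi, ylo:yhi, xlo:xhi]
        ball = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        sub = truth[zlo:zhi, ylo:yhi, xlo:xhi]
        carve = ball & (sub == cell_code)
        n_new = int(carve.sum())
        if n_new:
            sub[carve] = air_code
            air_count += n_new


def generate(spec: PhantomSpec) -> PhantomBundle:
    """Render a deterministic phantom bundle from a spec."""
    rng = np.random.default_rng(spec.seed)
    cm = ClassMap.default()
    z_ext, y_ext, x_ext = spec.shape
    offsets = _lamina_offsets(spec)  # (z, x)

    e, m = spec.epidermis_thickness, spec.mesophyll_thickness
    y0 = (y_ext - spec.leaf_thickness_voxels) // 2
    yy = np.arange(y_ext)[None, :, None]
    top = y0 + offsets[:, None, :]  # first adaxial-epidermis row per column
    truth = np.full(spec.shape, cm.code("background"), dtype=np.uint8)
    truth[(yy >= top) & (yy < top + e)] = cm.code("epidermis_adaxial")
    truth[(yy >= top + e) & (yy < top + e + m)] = cm.code("mesophyll_cell")
    truth[(yy >= top + e + m) & (yy < top + 2 * e + m)] = cm.code("epidermis_abaxial")

    # veins: cylinders along z at evenly spaced x positions, following the
    # lamina undulation at their own x so they stay mid-mesophyll
    xx = np.arange(x_ext)[None, None, :]
    cell_mask_code = cm.code("mesophyll_cell")
    for i in range(spec.vein_count):
        xc = int(round((i + 1) * x_ext / (spec.vein_count + 1)))
        yc = (y0 + e + m // 2 + offsets[:, xc])[:, None, None]
        d2 = (yy - yc) ** 2 + (xx - xc) ** 2
        in_meso = truth == cell_mask_code
        ring = (d2 <= (spec.vein_radius + spec.sheath_thickness) ** 2) & (
            d2 > spec.vein_radius**2
        )
        truth[ring & in_meso] = cm.code("bundle_sheath")
        truth[(d2 <= spec.vein_radius**2) & in_meso] = cm.code("vein")

    _carve_airspace(truth, cm, spec, offsets, rng)

    stacks = {}
    for modality in ("gridrec", "phase"):
        img = np.zeros(spec.shape, dtype=np.float32)
        for name, mean in spec.intensities[modality].items():
            img[truth == cm.code(name)] = mean
        img += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, spec.blur_sigma)
        stacks[modality] = ReconstructionStack(
            np.clip(np.rint(img), 0, 255).astype(np.uint8), spec.spacing, modality
        )

    truth_stack = LabelStack(truth, cm, spec.spacing)
    return PhantomBundle(
        stacks["gridrec"], stacks["phase"], truth_stack, spec,
        phantom_truth_traits(spec, truth_stack),
    )


def phantom_truth_traits(spec: PhantomSpec, truth: LabelStack) -> dict:
    """Closed-form and truth-measured trait expectations for a phantom."""
    sz, sy, sx = spec.spacing
    voxel_volume = sz * sy * sx
    counts = np.bincount(truth.voxels.ravel(), minlength=truth.class_map.sentinel)
    cm = truth.class_map
    meso = sum(
        int(counts[cm.code(n)])
        for n in ("mesophyll_cell", "airspace", "vein", "bundle_sheath")
    )
    return {
        "leaf_thickness_um": spec.leaf_thickness_voxels * sy,
        "mesophyll_thickness_um": spec.mesophyll_thickness * sy,
        "epidermis_thickness_um": spec.epidermis_thickness * sy,
        "volumes_um3": {
            name: float(counts[code] * voxel_volume) for name, code in cm.codes.items()
        },
        "porosity": float(counts[cm.code("airspace")] / meso),
        "leaf_area_um2": spec.shape[0] * spec.shape[2] * sz * sx,
        "expected_vein_voxels_analytic": spec.vein_count
        * np.pi
        * spec.vein_radius**2
        * spec.shape[0],
    }


def hand_label_sim(truth: LabelStack, n_slices: int, seed: int = 0) -> LabelStack:
    """Simulate hand labeling: n slices spread evenly across the stack.

    Returns a sparse LabelStack carrying truth labels on evenly spaced z
    indices and the unlabeled sentinel everywhere else.  The seed is part of
    the signature for symmetry with the other sampling helpers; even spacing
    makes the choice deterministic regardless.
    """
    nz = truth.shape[0]
    if not 1 <= n_slices <= nz:
        raise ValueError(f"n_slices must be within [1, {nz}], got {n_slices}")
    idx = np.unique(np.round(np.linspace(0, nz - 1, n_slices)).astype(int))
    sentinel = truth.class_map.sentinel
    vox = np.full(truth.shape, sentinel, dtype=np.min_scalar_type(sentinel))
    vox[idx] = truth.voxels[idx]
    return LabelStack(vox, truth.class_map, truth.spacing, tuple(int(i) for i in idx))
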