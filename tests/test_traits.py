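import math

import numpy as np
import pytest

from leafct.postprocess import EPIDERMES_CONNECTED
from leafct.stack_io import ClassMap, LabelStack
from leafct.traits import (
    compile_report,
    leaf_projected_area,
    mesophyll_surface_area,
    porosity,
    thickness_map,
    tissue_volumes,
)

CM = ClassMap.default()
SPACING = (0.1625, 0.325, 0.325)


def _labels(vox, spacing=(1, 1, 1), flags=()):
    return LabelStack(np.asarray(vox, np.int64), CM, spacing, flags=set(flags))


class TestThicknessMap:
    def test_uniform_slab_closed_form(self):
        vox = np.zeros((4, 60, 8), dtype=np.int64)
        vox[:, 10:50, :] = CM.code("mesophyll_cell")  # 40 voxels thick
        labels = _labels(vox, SPACING)
        m, mean, sd = thickness_map(labels, ("mesophyll_cell",))
        assert mean == pytest.approx(13.0)
        assert sd == 0.0
        assert np.nanmax(m) == np.nanmin(m) == pytest.approx(13.0)

    def test_hole_column_excluded(self):
        vox = np.zeros((2, 20, 6), dtype=np.int64)
        vox[:, 5:15, :] = CM.code("mesophyll_cell")
        vox[:, :, 3] = 0  # hole column
        labels = _labels(vox, (1, 1, 1))
        m, mean, sd = thickness_map(labels, ("mesophyll_cell",))
        assert np.isnan(m[0, 3])
        assert mean == pytest.approx(10.0) and sd == 0.0

    def test_stepped_slab_mean_and_sd(self):
        # direct column-count oracle: half 30 voxels, half 50
        vox = np.zeros((2, 60, 8), dtype=np.int64)
        vox[:, :30, :4] = CM.code("mesophyll_cell")
        vox[:, :50, 4:] = CM.code("mesophyll_cell")
        labels = _labels(vox, (1, 2.0, 1))
        _, mean, sd = thickness_map(labels, ("mesophyll_cell",))
        assert mean == pytest.approx(40 * 2.0)
        assert sd == pytest.approx(10 * 2.0)

    def test_absent_tissue_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            thickness_map(_labels(np.zeros((2, 2, 2))), ("vein",))

    def test_leaf_thicker_than_mesophyll_per_column(self, tiny_bundle):
        from leafct.traits import LEAF_TISSUES, MESOPHYLL_TISSUES

        leaf_m, _, _ = thickness_map(tiny_bundle.truth, LEAF_TISSUES)
        meso_m, _, _ = thickness_map(tiny_bundle.truth, MESOPHYLL_TISSUES)
        assert np.all(leaf_m >= meso_m)


class TestTissueVolumes:
    def test_voxel_count_arithmetic(self):
        vox = np.zeros((10, 10, 10), dtype=np.int64)
        vox.ravel()[:1000] = CM.code("vein")
        vols = tissue_volumes(_labels(vox, SPACING))
        voxel_vol = 0.1625 * 0.325 * 0.325
        assert vols["vein"] == pytest.approx(1000 * voxel_vol)
        assert vols["airspace"] == 0.0

    def test_conservation(self, tiny_bundle):
        vols = tissue_volumes(tiny_bundle.truth)
        sz, sy, sx = tiny_bundle.truth.spacing
        total = np.prod(tiny_bundle.truth.shape) * sz * sy * sx
        assert sum(vols.values()) == pytest.approx(total)


class TestMesophyllSurfaceArea:
    def _ball_stack(self, r, pad=4, spacing=(1, 1, 1)):
        n = 2 * (r + pad) + 1
        c = r + pad
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r * r
        vox = np.full((n, n, n), CM.code("airspace"), dtype=np.int64)
        vox[ball] = CM.code("mesophyll_cell")
        return _labels(vox, spacing)

    def test_digital_ball_matches_sphere_area(self):
        r = 20
        area = mesophyll_surface_area(self._ball_stack(r))
        assert area == pytest.approx(4 * math.pi * r * r, rel=0.03)

    def test_convergence_with_resolution(self):
        rel_err = []
        for r in (10, 20):
            area = mesophyll_surface_area(self._ball_stack(r))
            rel_err.append(abs(area - 4 * math.pi * r * r) / (4 * math.pi * r * r))
        assert rel_err[1] <= rel_err[0]

    def test_area_scales_with_spacing_squared(self):
        a1 = mesophyll_surface_area(self._ball_stack(8, spacing=(1, 1, 1)))
        a2 = mesophyll_surface_area(self._ball_stack(8, spacing=(2, 2, 2)))
        assert a2 == pytest.approx(4 * a1, rel=1e-6)

    def test_cell_touching_only_epidermis_gives_zero(self):
        vox = np.full((8, 8, 16), CM.code("epidermis_adaxial"), dtype=np.int64)
        vox[2:6, 2:6, 2:6] = CM.code("mesophyll_cell")  # fully wrapped in epidermis
        vox[:, :, 12:] = CM.code("airspace")  # airspace far away, no adjacency
        assert mesophyll_surface_area(_labels(vox)) == 0.0

    def test_missing_class_rejected(self):
        vox = np.full((4, 4, 4), CM.code("mesophyll_cell"), dtype=np.int64)
        with pytest.raises(ValueError, match="airspace"):
            mesophyll_surface_area(_labels(vox))


class TestCompileReport:
    def test_phantom_truth_matches_expectations(self, tiny_bundle):
        rep = compile_report(tiny_bundle.truth)
        exp = tiny_bundle.expected_traits
        assert rep.thickness_leaf_um == pytest.approx(exp["leaf_thickness_um"])
        assert rep.thickness_leaf_sd_um == 0.0
        assert rep.thickness_epidermis_adaxial_um == pytest.approx(
            exp["epidermis_thickness_um"]
        )
        assert rep.porosity == pytest.approx(exp["porosity"])
        for name, v in exp["volumes_um3"].items():
            assert rep.volumes_um3[name] == pytest.approx(v)
        assert rep.leaf_area_um2 == pytest.approx(exp["leaf_area_um2"])

    def test_flagged_stack_withholds_epidermis_thickness(self, tiny_bundle):
        flagged = LabelStack(
            tiny_bundle.truth.voxels, CM, tiny_bundle.truth.spacing,
            flags={EPIDERMES_CONNECTED},
        )
        rep = compile_report(flagged)
        assert math.isnan(rep.thickness_epidermis_adaxial_um)
        assert math.isnan(rep.thickness_mesophyll_um)
        assert rep.thickness_leaf_um > 0  # whole-leaf metrics still reported
        assert EPIDERMES_CONNECTED in rep.flags

    def test_empty_vein_class_reports_zero(self):
        vox = np.full((4, 12, 4), CM.code("airspace"), dtype=np.int64)
        vox[:, 0, :] = CM.code("epidermis_adaxial")
        vox[:, -1, :] = CM.code("epidermis_abaxial")
        vox[:, 5:7, :] = CM.code("mesophyll_cell")
        rep = compile_report(_labels(vox))
        assert rep.volumes_um3["vein"] == 0.0

    def test_translation_invariance(self, tiny_bundle):
        rolled = LabelStack(
            np.roll(tiny_bundle.truth.voxels, 3, axis=2), CM, tiny_bundle.truth.spacing
        )
        a = compile_report(tiny_bundle.truth)
        b = compile_report(rolled)
        assert a.thickness_leaf_um == pytest.approx(b.thickness_leaf_um)
        assert a.porosity == pytest.approx(b.porosity)
        assert a.volumes_um3 == b.volumes_um3

    def test_csv_row_emitted(self, tiny_bundle, tmp_path):
        rep = compile_report(tiny_bundle.truth)
        df = rep.to_frame()
        p = tmp_path / "traits.csv"
        df.to_csv(p, index=False)
        assert p.exists() and len(df) == 1
        assert "volume_vein_um3" in df.columns


def test_porosity_of_all_air_mesophyll_is_bounded():
    vox = np.full((2, 4, 4), CM.code("airspace"), dtype=np.int64)
    assert porosity(_labels(vox)) == 1.0


def test_projected_area_counts_leaf_columns():
    vox = np.zeros((2, 6, 5), dtype=np.int64)
    vox[:, 2, :3] = CM.code("mesophyll_cell")
    area = leaf_projected_area(_labels(vox, (2.0, 1.0, 3.0)))
    assert area == pytest.approx(2 * 3 * 2.0 * 3.0)
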