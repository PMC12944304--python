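import numpy as np
import pytest
from hypothesis import given, strategies as st

import nasofilm as nf
from nasofilm.datasets import unilateral_dims
from nasofilm.geometry import Orientation


class TestPlate:
    def test_area_and_outlet_chain(self):
        m = nf.build_plate_mesh(20.0, 40, 60.0)
        assert m.face_area.sum() == pytest.approx(400.0)
        assert len(m.outlet_edges) == 40  # one chain along the lower edge
        assert set(m.face_region) == {"plate"}

    def test_horizontal_gravity_is_normal(self):
        m = nf.build_plate_mesh(20.0, 2, 0.0)
        assert m.n_faces == 8
        g_tau = m.gravity_vector - (m.gravity_vector @ m.face_normal[0]) * m.face_normal[0]
        assert np.linalg.norm(g_tau) == pytest.approx(0.0, abs=1e-12)

    def test_vertical_gravity_fully_tangential(self):
        m = nf.build_plate_mesh(10.0, 40, 90.0)
        assert m.face_area.sum() == pytest.approx(100.0)
        # tangential component of unit gravity has magnitude 1
        tang = m.gravity_vector - (m.gravity_vector @ m.face_normal[0]) * m.face_normal[0]
        assert np.linalg.norm(tang) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "args", [(-1, 10, 0), (10, 1, 0), (10, 10, 190)]
    )
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            nf.build_plate_mesh(*args)


class TestNasalSurrogate:
    def test_region_areas_match_targets(self, surrogate_45):
        areas = surrogate_45.region_areas()
        for region, d in unilateral_dims().items():
            target = 100.0 * d["area_cm2"]
            assert areas[region] == pytest.approx(target, rel=0.02), region

    def test_orientation_rotates_gravity_only(self):
        supine = nf.build_nasal_surrogate(orientation=Orientation(0.0), resolution=2.5)
        tilted = nf.build_nasal_surrogate(orientation=Orientation(45.0), resolution=2.5)
        np.testing.assert_allclose(supine.vertices, tilted.vertices)
        np.testing.assert_array_equal(supine.faces, tilted.faces)
        np.testing.assert_array_equal(supine.face_region, tilted.face_region)
        # gravity rotated by 45 degrees about the lateral (y) axis
        c45 = np.cos(np.radians(45.0))
        np.testing.assert_allclose(supine.gravity_vector, [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(tilted.gravity_vector, [c45, 0, -c45], atol=1e-12)

    def test_refinement_convergence(self):
        coarse = nf.build_nasal_surrogate(resolution=2.6)
        fine = nf.build_nasal_surrogate(resolution=1.3)
        ac, af = coarse.region_areas(), fine.region_areas()
        for r in ac:
            assert ac[r] == pytest.approx(af[r], rel=0.02)

    def test_single_region_tube(self):
        dims = {"turbinate": {"area_cm2": 10.0, "volume_cm3": 0.8}}
        m = nf.build_nasal_surrogate(dims, resolution=1.5)
        assert set(m.face_region) == {"turbinate"}
        assert m.face_area.sum() == pytest.approx(1000.0, rel=0.02)

    def test_missing_area_rejected(self):
        with pytest.raises(ValueError):
            nf.build_nasal_surrogate({"turbinate": {"volume_cm3": 1.0}})

    def test_outlet_is_at_distal_end(self, surrogate_45):
        con = surrogate_45.connectivity
        outlet_regions = set(
            surrogate_45.face_region[con.outlet_faces].tolist()
        )
        assert outlet_regions == {"larynx"}

    def test_normals_unit_and_areas_positive(self, surrogate_45):
        norms = np.linalg.norm(surrogate_45.face_normal, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)
        assert (surrogate_45.face_area > 0).all()


class TestHoldingCapacity:
    def test_plate_capacity(self):
        m = nf.build_plate_mesh(20.0, 10, 60.0)
        assert nf.holding_capacity(m, 0.324) == pytest.approx(0.1296)
        assert nf.holding_capacity(m, 0.0) == 0.0

    def test_anterior_capacity(self, surrogate_45):
        cap = nf.holding_capacity(
            surrogate_45, 0.324, ["vestibule", "valve", "turbinate"]
        )
        # 14.27 cm^2 of anterior surface at 0.324 mm holds ~0.462 mL
        assert cap == pytest.approx(0.462, rel=0.02)

    def test_empty_selection_is_zero(self, surrogate_45):
        assert nf.holding_capacity(surrogate_45, 0.324, []) == 0.0

    @given(h=st.floats(0.05, 1.0), scale=st.floats(0.1, 5.0))
    def test_linear_in_hmax(self, h, scale):
        m = nf.build_plate_mesh(10.0, 4, 45.0)
        assert nf.holding_capacity(m, h * scale) == pytest.approx(
            scale * nf.holding_capacity(m, h)
        )

    def test_additive_over_regions(self, surrogate_45):
        regions = list(np.unique(surrogate_45.face_region))
        parts = sum(
            nf.holding_capacity(surrogate_45, 0.22, [r]) for r in regions
        )
        assert parts == pytest.approx(nf.holding_capacity(surrogate_45, 0.22))


def test_mesh_io_roundtrip(tmp_path):
    m = nf.build_plate_mesh(10.0, 4, 30.0)
    path = tmp_path / "plate.obj"
    nf.save_mesh(m, path)
    back = nf.load_mesh(path)
    np.testing.assert_allclose(back.vertices, m.vertices, atol=1e-6)
    np.testing.assert_array_equal(back.faces, m.faces)
    np.testing.assert_array_equal(back.face_region, m.face_region)
    np.testing.assert_allclose(back.gravity_vector, m.gravity_vector)
    assert sorted(map(tuple, back.outlet_edges.tolist())) == sorted(
        map(tuple, m.outlet_edges.tolist())
    )
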