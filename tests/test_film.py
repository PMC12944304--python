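import numpy as np
import pytest

import nasofilm as nf
from nasofilm.film import (
    CFLError,
    FilmState,
    FluidProps,
    apply_hmax_constraint,
    init_film,
    run_film,
    stable_dt,
    step_film,
)
from nasofilm.transport import DepositionMap


def _uniform_state(mesh, h_mm):
    return FilmState(
        t=0.0,
        h_mm=np.full(mesh.n_faces, float(h_mm)),
        velocity_m_s=np.zeros((mesh.n_faces, 3)),
    )


class TestInitFilm:
    def test_uniform_dose_gives_hmax_height(self):
        m = nf.build_plate_mesh(20.0, 10, 60.0)
        vol_nL = 0.1296e6 * m.face_area / m.face_area.sum()
        dep = DepositionMap(mesh=m, face_volume_nL=vol_nL)
        st = init_film(dep, m)
        np.testing.assert_allclose(st.h_mm, 0.324, rtol=1e-12)

    def test_empty_map_zero_film(self):
        m = nf.build_plate_mesh(10.0, 4, 0.0)
        st = init_film(DepositionMap(mesh=m, face_volume_nL=np.zeros(m.n_faces)), m)
        assert st.film_volume_mL(m) == 0.0

    def test_volume_preserved(self, deposition_45, surrogate_45):
        st = init_film(deposition_45, surrogate_45)
        assert st.film_volume_mL(surrogate_45) == pytest.approx(
            deposition_45.face_volume_nL.sum() * 1e-6, rel=1e-12
        )


class TestStepFilm:
    def test_horizontal_subcapacity_equilibrium(self):
        m = nf.build_plate_mesh(20.0, 10, 0.0)
        props = FluidProps()
        st = _uniform_state(m, 0.2)
        st2 = step_film(st, props, m, stable_dt(st, props, m))
        assert np.abs(st2.h_mm - 0.2).max() < 1e-12
        assert np.linalg.norm(st2.velocity_m_s, axis=1).max() < 1e-12

    @pytest.mark.parametrize("tilt,h_mm", [(90.0, 0.1), (60.0, 0.12)])
    def test_terminal_speed_matches_closed_form(self, tilt, h_mm):
        """Gravity/wall-drag balance: V = g_tau h^2 / (3 nu)."""
        m = nf.build_plate_mesh(20.0, 20, tilt)
        props = FluidProps(adhesion=False)
        st = _uniform_state(m, h_mm)
        g_tau = 9.81 * np.sin(np.radians(tilt))
        v_ref = g_tau * (h_mm * 1e-3) ** 2 / (3 * props.kinematic_viscosity_m2_s)
        while st.t < 0.05:
            st = step_film(st, props, m, min(stable_dt(st, props, m), 0.05 - st.t))
        cy = m.face_centroid[:, 1]
        band = (cy > 4) & (cy < 10)  # below the drainage front from the top
        speeds = np.linalg.norm(st.velocity_m_s[band], axis=1)
        assert np.median(speeds) == pytest.approx(v_ref, rel=0.01)

    def test_cfl_violation_reports_required_dt(self):
        m = nf.build_plate_mesh(20.0, 10, 90.0)
        props = FluidProps(adhesion=False)
        st = _uniform_state(m, 0.2)
        st.velocity_m_s[:, 1] = -0.5
        with pytest.raises(CFLError) as err:
            step_film(st, props, m, 1.0)
        assert 0 < err.value.dt_required < 1.0

    def test_mass_conserved_without_outlet_flow(self):
        m = nf.build_plate_mesh(20.0, 10, 45.0)
        props = FluidProps(adhesion=False)
        st = _uniform_state(m, 0.15)
        v0 = st.film_volume_mL(m)
        for _ in range(20):
            st = step_film(st, props, m, stable_dt(st, props, m))
        assert st.total_volume_mL(m) == pytest.approx(v0, rel=1e-12)


class TestHmaxConstraint:
    def test_identity_below_capacity(self):
        m = nf.build_plate_mesh(20.0, 10, 60.0)
        st = _uniform_state(m, 0.2)
        st2 = apply_hmax_constraint(st, m, FluidProps(h_max_mm=0.324))
        np.testing.assert_array_equal(st2.h_mm, st.h_mm)
        assert st2.runoff_mL["outlet"] == 0.0

    def test_saturated_chain_passes_excess_to_outlet(self):
        """One face at twice capacity on a fully saturated tilted plate:
        the excess threads through the saturated field and leaves, and
        the field stays exactly at capacity."""
        m = nf.build_plate_mesh(20.0, 8, 60.0)
        props = FluidProps(h_max_mm=0.3)
        st = _uniform_state(m, 0.3)
        k = m.n_faces // 2
        st.h_mm[k] = 0.6
        excess_mL = 0.3 * m.face_area[k] / 1000.0
        v0 = st.film_volume_mL(m)
        st2 = apply_hmax_constraint(st, m, props)
        assert st2.h_mm.max() <= 0.3 + 1e-12
        assert st2.runoff_mL["outlet"] == pytest.approx(excess_mL, rel=1e-9)
        assert st2.total_volume_mL(m) == pytest.approx(v0, rel=1e-12)

    def test_overloaded_plate_sheds_to_capacity(self):
        m = nf.build_plate_mesh(20.0, 10, 60.0)
        props = FluidProps(h_max_mm=0.282)
        st = _uniform_state(m, 0.5)
        st2 = apply_hmax_constraint(st, m, props)
        assert st2.h_mm.max() <= 0.282 + 1e-12
        assert st2.runoff_mL["outlet"] == pytest.approx(
            (0.5 - 0.282) * 0.4, rel=1e-9
        )

    def test_closed_basin_pools(self):
        """A mesh with no outlet cannot shed; the excess is flagged."""
        m = nf.build_plate_mesh(10.0, 4, 60.0)
        m = nf.SurfaceMesh(
            vertices=m.vertices,
            faces=m.faces,
            face_region=m.face_region,
            gravity_vector=m.gravity_vector,
            outlet_edges=np.zeros((0, 2), dtype=int),
        )
        st = _uniform_state(m, 0.5)
        v0 = st.film_volume_mL(m)
        st2 = apply_hmax_constraint(st, m, FluidProps(h_max_mm=0.3), max_passes=500)
        assert st2.pooled_mL > 0
        assert st2.runoff_mL["outlet"] == 0.0
        assert st2.total_volume_mL(m) == pytest.approx(v0, rel=1e-12)

    def test_angle_dependent_hmax_table(self):
        table = {45.0: 0.324, 60.0: 0.293, 90.0: 0.220}
        props = FluidProps(h_max_mm=table)
        m45 = nf.build_plate_mesh(20.0, 4, 45.0)
        m90 = nf.build_plate_mesh(20.0, 4, 90.0)
        assert props.hmax_per_face(m45)[0] == pytest.approx(0.324)
        assert props.hmax_per_face(m90)[0] == pytest.approx(0.220)
        with pytest.raises(ValueError):
            FluidProps(h_max_mm={45.0: 0.2, 90.0: 0.3})  # increasing


class TestRunFilm:
    def test_tilted_coupon_retains_measured_thickness(self):
        """A 60-degree coupon loaded above capacity settles at the
        measured mean retained thickness when h_max is set to it."""
        m = nf.build_plate_mesh(20.0, 10, 60.0)
        props = FluidProps(h_max_mm=0.29)
        dep = DepositionMap(
            mesh=m, face_volume_nL=0.25e6 * m.face_area / m.face_area.sum()
        )
        run = run_film(init_film(dep, m), props, m, t_end=0.5)
        mean_h = float(
            (run.state.h_mm * m.face_area).sum() / m.face_area.sum()
        )
        assert 0.282 <= mean_h <= 0.293
        assert run.state.runoff_mL["outlet"] == pytest.approx(
            0.25 - 0.29 * 0.4, rel=1e-6
        )

    def test_checkpoint_conservation(self, deposition_45, surrogate_45):
        mesh = surrogate_45
        dep = deposition_45.scaled(2.0)  # 0.5 mL
        props = FluidProps(h_max_mm=0.324)
        run = run_film(
            init_film(dep, mesh), props, mesh, t_end=0.3,
            checkpoints=(0.02, 0.1, 0.2),
        )
        total = dep.face_volume_nL.sum() * 1e-6
        assert len(run.snapshots) == 3
        for t, vols, runoff, h in run.snapshots:
            on_mesh = float((h * mesh.face_area).sum() / 1000.0)
            assert on_mesh + sum(runoff.values()) == pytest.approx(
                total, rel=1e-8
            )

    def test_film_stabilises(self, deposition_45, surrogate_45):
        run = run_film(
            init_film(deposition_45, surrogate_45),
            FluidProps(h_max_mm=0.324),
            surrogate_45,
            t_end=2.0,
        )
        assert run.converged_at is not None and run.converged_at < 1.0
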