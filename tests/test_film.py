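"""Wall-film solver: operators, forcing, stepping, drainage, conservation."""

import numpy as np
import pandas as pd
import pytest

from nasospray import geometry as geo
from nasospray.film import (FilmError, FilmSolverParams, FilmState,
                            FluidProperties, SurfaceOperators,
                            accrete_deposits, adaptive_dt, advance_film,
                            compute_forcing, run_film, surface_operators)

WATER = FluidProperties()
G_DOWN = np.array([0.0, 0.0, -9.81])


@pytest.fixture(scope="module")
def strip():
    """Vertical wall strip (x-z plane), periodic along the slope."""
    return geo.flat_patch_mesh(nx=6, ny=40, lx=0.01, ly=0.05,
                               normal_axis="y", periodic_y=True)


@pytest.fixture(scope="module")
def strip_ops(strip):
    return SurfaceOperators(strip)


class TestSurfaceOperators:
    def test_gradient_of_constant_is_zero(self, flat_patch_ops):
        field = np.full(flat_patch_ops.mesh.n_faces, 2.5)
        assert np.abs(flat_patch_ops.gradient(field)).max() == 0.0

    def test_laplacian_of_linear_field_vanishes(self, flat_patch, flat_patch_ops):
        c = flat_patch.face_centroid
        lap = flat_patch_ops.laplacian(3.0 * c[:, 0] - 1.2 * c[:, 1])
        interior = _interior(flat_patch, flat_patch_ops)
        assert np.abs(lap[interior]).max() < 1e-8

    def test_laplacian_of_quadratic_near_two(self, flat_patch, flat_patch_ops):
        c = flat_patch.face_centroid
        lap = flat_patch_ops.laplacian(c[:, 0] ** 2)
        deep = ((c[:, 0] > 0.2) & (c[:, 0] < 0.8)
                & (c[:, 1] > 0.2) & (c[:, 1] < 0.8))
        assert lap[deep].mean() == pytest.approx(2.0, rel=0.05)

    def test_gradient_lies_in_tangent_plane(self, nose_mesh, nose_ops):
        field = nose_mesh.face_centroid[:, 2]
        g = nose_ops.gradient(field)
        dot = np.einsum("ij,ij->i", g, nose_mesh.face_normal)
        assert np.abs(dot).max() < 1e-10

    def test_factory_function(self, flat_patch):
        assert isinstance(surface_operators(flat_patch), SurfaceOperators)


def _interior(mesh, ops):
    """Faces whose whole one-ring is interior (full gradient stencils)."""
    counts = np.bincount(np.concatenate([ops.fa, ops.fb]),
                         minlength=mesh.n_faces)
    full = counts == 3
    ok = full.copy()
    for k in range(len(ops.fa)):
        a, b = ops.fa[k], ops.fb[k]
        if not full[b]:
            ok[a] = False
        if not full[a]:
            ok[b] = False
    return ok


class TestAccretion:
    def test_single_droplet_height_is_volume_over_area(self, flat_patch):
        ops = SurfaceOperators(flat_patch)
        v = 3.3e-9
        rec = pd.DataFrame({"face_id": [17], "volume_m3": [v],
                            "vx": [0.1], "vy": [0.0], "vz": [0.0]})
        state = accrete_deposits(FilmState.zero(flat_patch), rec, flat_patch,
                                 ops)
        assert state.h[17] == pytest.approx(v / flat_patch.face_area[17],
                                            rel=1e-12)
        assert state.accreted_volume == pytest.approx(v)

    def test_empty_records_leave_state_unchanged(self, flat_patch):
        state = FilmState.zero(flat_patch)
        out = accrete_deposits(state, pd.DataFrame(), flat_patch)
        assert np.array_equal(out.h, state.h)

    def test_opposed_impacts_cancel_momentum_but_add_mass(self, flat_patch):
        v = 1e-9
        rec = pd.DataFrame({"face_id": [5, 5], "volume_m3": [v, v],
                            "vx": [2.0, -2.0], "vy": [0.0, 0.0],
                            "vz": [0.0, 0.0]})
        state = accrete_deposits(FilmState.zero(flat_patch), rec, flat_patch)
        assert state.h[5] == pytest.approx(2 * v / flat_patch.face_area[5])
        assert np.abs(state.V[5]).max() < 1e-14

    def test_unknown_face_rejected(self, flat_patch):
        rec = pd.DataFrame({"face_id": [10 ** 6], "volume_m3": [1e-9]})
        with pytest.raises(IndexError):
            accrete_deposits(FilmState.zero(flat_patch), rec, flat_patch)


class TestForcing:
    def test_dry_state_has_no_pressures(self, flat_patch, flat_patch_ops):
        state = FilmState.zero(flat_patch)
        f = compute_forcing(state, flat_patch, WATER, G_DOWN, None,
                            flat_patch_ops)
        assert np.all(f.P_h == 0.0) and np.all(f.P_sigma == 0.0)

    def test_horizontal_face_has_no_tangential_gravity(self, flat_patch,
                                                       flat_patch_ops):
        state = FilmState.zero(flat_patch)
        f = compute_forcing(state, flat_patch, WATER, G_DOWN, None,
                            flat_patch_ops)
        assert np.abs(f.g_tau).max() < 1e-12

    def test_vertical_face_keeps_full_gravity(self, strip, strip_ops):
        state = FilmState.zero(strip)
        f = compute_forcing(state, strip, WATER, G_DOWN, None, strip_ops)
        assert np.allclose(np.linalg.norm(f.g_tau, axis=1), 9.81)

    def test_film_weight_pressure_on_floor(self, flat_patch, flat_patch_ops):
        # liquid resting on a horizontal floor: spreading pressure rho g h
        h0 = 2e-4
        state = FilmState(h=np.full(flat_patch.n_faces, h0),
                          V=np.zeros((flat_patch.n_faces, 3)))
        f = compute_forcing(state, flat_patch, WATER, G_DOWN, None,
                            flat_patch_ops)
        assert np.allclose(f.P_h, WATER.rho_l * 9.81 * h0, rtol=1e-12)
        assert np.abs(f.P_sigma).max() < 1e-8   # uniform film


class TestAdvanceFilm:
    def test_dry_surface_is_invariant(self, flat_patch, flat_patch_ops):
        params = FilmSolverParams(dt_max=1e-4)
        state = FilmState.zero(flat_patch)
        f = compute_forcing(state, flat_patch, WATER, G_DOWN, None,
                            flat_patch_ops)
        out = advance_film(state, f, params, 1e-5, flat_patch,
                           flat_patch_ops, WATER)
        assert np.all(out.h == 0.0) and np.all(out.V == 0.0)

    def test_uniform_horizontal_film_is_fixed_point(self, flat_patch,
                                                    flat_patch_ops):
        params = FilmSolverParams(dt_max=1e-4)
        state = FilmState(h=np.full(flat_patch.n_faces, 3e-4),
                          V=np.zeros((flat_patch.n_faces, 3)))
        for _ in range(20):
            f = compute_forcing(state, flat_patch, WATER, G_DOWN, None,
                                flat_patch_ops)
            state = advance_film(state, f, params, 1e-4, flat_patch,
                                 flat_patch_ops, WATER)
        assert np.abs(state.V).max() == 0.0
        assert np.allclose(state.h, 3e-4)

    def test_dt_outside_bounds_rejected(self, flat_patch, flat_patch_ops):
        params = FilmSolverParams(dt_min=1e-6, dt_max=1e-5)
        state = FilmState.zero(flat_patch)
        f = compute_forcing(state, flat_patch, WATER, G_DOWN, None,
                            flat_patch_ops)
        with pytest.raises(FilmError):
            advance_film(state, f, params, 1e-3, flat_patch, flat_patch_ops,
                         WATER)

    def test_nusselt_drainage_speed(self, strip, strip_ops):
        # steady vertical drainage of a 100 µm water film: g h²/(3 nu)
        params = FilmSolverParams(dt_max=2e-5, h_pin=1e-6)
        state = FilmState(h=np.full(strip.n_faces, 1e-4),
                          V=np.zeros((strip.n_faces, 3)))
        for _ in range(2500):
            dt = adaptive_dt(state, strip_ops, params)
            f = compute_forcing(state, strip, WATER, G_DOWN, None, strip_ops)
            state = advance_film(state, f, params, dt, strip, strip_ops,
                                 WATER)
        expected = 9.81 * (1e-4) ** 2 / (3 * 1e-6)
        assert expected == pytest.approx(0.0327, abs=3e-5)
        mean_speed = np.linalg.norm(state.V, axis=1).mean()
        assert mean_speed == pytest.approx(expected, rel=0.02)
        assert np.allclose(state.h, 1e-4, rtol=1e-9)  # uniform transport

    def test_height_stays_nonnegative_under_strong_forcing(self, strip,
                                                           strip_ops):
        params = FilmSolverParams(dt_max=1e-4, h_pin=1e-6)
        rng = np.random.default_rng(3)
        state = FilmState(h=rng.uniform(0, 5e-4, strip.n_faces),
                          V=np.zeros((strip.n_faces, 3)))
        for _ in range(300):
            dt = adaptive_dt(state, strip_ops, params)
            f = compute_forcing(state, strip, WATER, G_DOWN, None, strip_ops)
            state = advance_film(state, f, params, dt, strip, strip_ops,
                                 WATER)
        assert state.h.min() >= 0.0

    def test_pinned_film_below_threshold_does_not_move(self, strip,
                                                       strip_ops):
        # film thinner than the holding capacity stays in its footprint
        params = FilmSolverParams(dt_max=1e-4, h_pin=2e-4)
        c = strip.face_centroid
        blob = np.where(np.abs(c[:, 2] - 0.025) < 0.005, 1e-4, 0.0)
        state = FilmState(h=blob.copy(), V=np.zeros((strip.n_faces, 3)))
        for _ in range(200):
            dt = adaptive_dt(state, strip_ops, params)
            f = compute_forcing(state, strip, WATER, G_DOWN, None, strip_ops)
            state = advance_film(state, f, params, dt, strip, strip_ops,
                                 WATER)
        assert np.array_equal(state.h, blob)

    def test_reversing_gravity_mirrors_migration(self):
        mesh = geo.flat_patch_mesh(nx=4, ny=20, lx=0.004, ly=0.02,
                                   normal_axis="y")
        ops = SurfaceOperators(mesh)
        params = FilmSolverParams(dt_max=1e-4, h_pin=1e-6)
        c = mesh.face_centroid
        blob = np.where(np.abs(c[:, 2] - 0.01) < 0.003, 3e-4, 0.0)

        def centroid_after(gz):
            state = FilmState(h=blob.copy(), V=np.zeros((mesh.n_faces, 3)))
            for _ in range(300):
                dt = adaptive_dt(state, ops, params)
                f = compute_forcing(state, mesh, WATER, [0, 0, gz], None, ops)
                state = advance_film(state, f, params, dt, mesh, ops, WATER)
            w = state.h * mesh.face_area
            return (w * c[:, 2]).sum() / w.sum()

        z_down = centroid_after(-9.81)
        z_up = centroid_after(+9.81)
        assert z_down < 0.01 < z_up
        assert z_down - 0.01 == pytest.approx(0.01 - z_up, rel=1e-6)


class TestAdaptiveDt:
    def test_resting_film_uses_dt_max(self, flat_patch, flat_patch_ops):
        params = FilmSolverParams(dt_max=5e-5)
        state = FilmState.zero(flat_patch)
        assert adaptive_dt(state, flat_patch_ops, params) == 5e-5

    def test_courant_limit_edge_over_speed(self):
        mesh = geo.flat_patch_mesh(nx=2, ny=2, lx=2e-4, ly=2e-4)
        ops = SurfaceOperators(mesh)
        params = FilmSolverParams(dt_min=1e-9, dt_max=1.0, courant=1.0)
        state = FilmState(h=np.full(mesh.n_faces, 1e-4),
                          V=np.zeros((mesh.n_faces, 3)))
        state.V[0] = [1.0, 0.0, 0.0]
        assert adaptive_dt(state, ops, params) == pytest.approx(1e-4)

    def test_clamped_at_dt_min_with_warning(self, flat_patch,
                                            flat_patch_ops):
        params = FilmSolverParams(dt_min=1e-5, dt_max=1e-4)
        state = FilmState(h=np.full(flat_patch.n_faces, 1e-4),
                          V=np.zeros((flat_patch.n_faces, 3)))
        state.V[:, 0] = 1e5
        with pytest.warns(RuntimeWarning):
            dt = adaptive_dt(state, flat_patch_ops, params)
        assert dt == params.dt_min


class TestRunFilm:
    def test_zero_deposits_stay_zero(self, strip, strip_ops):
        params = FilmSolverParams(dt_max=1e-4, end_time=0.005)
        state, snaps = run_film(strip, pd.DataFrame(), WATER, G_DOWN, None,
                                params, snapshot_times=[0.002],
                                ops=strip_ops)
        assert state.total_volume(strip) == 0.0
        assert all(s.total_volume(strip) == 0.0 for _, s in snaps)

    def test_total_volume_equals_accreted(self, strip, strip_ops):
        rec = pd.DataFrame({
            "face_id": [10, 50, 90],
            "volume_m3": [2e-9, 1e-9, 3e-9],
            "vx": [0.0] * 3, "vy": [0.0] * 3, "vz": [-1.0] * 3,
            "t": [0.0, 1e-3, 2e-3],
        })
        params = FilmSolverParams(dt_max=1e-4, end_time=0.02, h_pin=1e-6)
        state, _ = run_film(strip, rec, WATER, G_DOWN, None, params,
                            ops=strip_ops)
        assert state.accreted_volume == pytest.approx(6e-9, rel=1e-12)
        assert state.total_volume(strip) == pytest.approx(
            state.accreted_volume, rel=1e-10)

    def test_snapshots_cover_requested_times(self, strip, strip_ops):
        rec = pd.DataFrame({"face_id": [30], "volume_m3": [5e-9],
                            "vx": [0.0], "vy": [0.0], "vz": [0.0],
                            "t": [0.0]})
        params = FilmSolverParams(dt_max=1e-4, end_time=0.01)
        _, snaps = run_film(strip, rec, WATER, G_DOWN, None, params,
                            snapshot_times=[0.002, 0.005], ops=strip_ops)
        assert [t for t, _ in snaps] == [0.002, 0.005]
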