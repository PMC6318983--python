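import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from surfelseg import (
    Image3D,
    Params,
    f_dist_profile,
    image_force,
    local_max_offset,
    make_surfel,
    pair_interaction,
    pair_interaction_repulsive_only,
    sphere_shell,
)
from surfelseg.forces import image_forces_bulk, pair_forces_bulk

from conftest import hex_patch


class TestDistanceProfile:
    def test_vanishes_at_equilibrium(self):
        assert f_dist_profile(1.0) == 0.0

    def test_harmonic_repulsion_below_d0(self):
        assert f_dist_profile(0.5) == pytest.approx(-0.5)
        assert f_dist_profile(0.9) == pytest.approx(-0.1)

    def test_bond_vanishes_at_infinity(self):
        assert abs(f_dist_profile(10.0)) < 1e-10

    def test_attractive_above_d0(self):
        x = np.linspace(1.01, 2.5, 40)
        assert np.all(f_dist_profile(x) > 0)

    def test_continuous_at_d0(self):
        eps = 1e-8
        assert abs(f_dist_profile(1 + eps) - f_dist_profile(1 - eps)) < 1e-6

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            f_dist_profile(0.0)


class TestPairInteraction:
    def test_equilibrium_orthogonal_normals_all_zero(self, params):
        d0 = params.d0
        si = make_surfel((0, 0, 0), (0, 0, 1), 0)
        sj = make_surfel((d0, 0, 0), (0, 0, 1), 0)
        pi = pair_interaction(si, sj, params)
        assert np.allclose(pi.f_dist, 0, atol=1e-12)
        assert np.allclose(pi.f_plane, 0, atol=1e-12)
        assert np.allclose(pi.t_tilt, 0, atol=1e-12)

    def test_normal_along_u_feels_restoring_torque(self):
        # n_i = u: the tilt torque removes the normal component along u,
        # so it points against u with magnitude k_tilt.
        p = Params(d0=3.0, k_tilt=0.5)
        si = make_surfel((0, 0, 0), (1, 0, 0), 0)
        sj = make_surfel((3.0, 0, 0), (0, 0, 1), 0)
        pi = pair_interaction(si, sj, p)
        assert np.allclose(pi.f_dist, 0, atol=1e-12)
        assert np.allclose(pi.t_tilt, (-0.5, 0, 0), atol=1e-12)
        # F_plane = k_plane*(u.(n_i+n_j))*n_i with u.(n_i+n_j) = 1
        assert np.allclose(pi.f_plane, p.k_plane * np.array([1.0, 0, 0]))

    def test_coincident_positions_rejected(self, params):
        s = make_surfel((1, 1, 1), (0, 0, 1), 0)
        with pytest.raises(ValueError):
            pair_interaction(s, s, params)

    def test_f_dist_antisymmetry(self, params, rng):
        for _ in range(20):
            pi_pos = rng.uniform(0, 10, 3)
            pj_pos = pi_pos + rng.uniform(-4, 4, 3)
            if np.linalg.norm(pj_pos - pi_pos) < 1e-3:
                continue
            si = make_surfel(pi_pos, rng.standard_normal(3), 0)
            sj = make_surfel(pj_pos, rng.standard_normal(3), 0)
            fij = pair_interaction(si, sj, params).f_dist
            fji = pair_interaction(sj, si, params).f_dist
            assert np.allclose(fij, -fji, atol=1e-12)

    def test_rotation_equivariance(self, params, rng):
        R = Rotation.random(random_state=3).as_matrix()
        pi_pos, pj_pos = np.array([1.0, 2, 3]), np.array([3.0, 1.5, 3.5])
        ni, nj = np.array([0, 0, 1.0]), np.array([0.2, 0, 1.0])
        si, sj = make_surfel(pi_pos, ni, 0), make_surfel(pj_pos, nj, 0)
        sir = make_surfel(R @ pi_pos, R @ si.normal, 0)
        sjr = make_surfel(R @ pj_pos, R @ sj.normal, 0)
        a = pair_interaction(si, sj, params)
        b = pair_interaction(sir, sjr, params)
        assert np.allclose(R @ a.f_dist, b.f_dist, atol=1e-10)
        assert np.allclose(R @ a.f_plane, b.f_plane, atol=1e-10)
        assert np.allclose(R @ a.t_tilt, b.t_tilt, atol=1e-10)

    def test_hexagonal_patch_is_fixed_point(self, params):
        surfels = hex_patch(params.d0)
        center = surfels[0]
        F = np.zeros(3)
        T = np.zeros(3)
        for nb in surfels[1:]:
            pi = pair_interaction(center, nb, params)
            F += pi.force
            T += pi.t_tilt
        assert np.linalg.norm(F) < 1e-12
        assert np.linalg.norm(T) < 1e-12


class TestRepulsiveOnly:
    def test_no_interaction_beyond_d0(self, params):
        si = make_surfel((0, 0, 0), (0, 0, 1), 0)
        sj = make_surfel((1.5 * params.d0, 0, 0), (0, 0, 1), 1)
        pi = pair_interaction_repulsive_only(si, sj, params)
        assert np.allclose(pi.f_dist, 0)
        assert np.allclose(pi.f_plane, 0)
        assert np.allclose(pi.t_tilt, 0)

    def test_harmonic_branch_below_d0(self, params):
        si = make_surfel((0, 0, 0), (0, 0, 1), 0)
        sj = make_surfel((0.5 * params.d0, 0, 0), (0, 0, 1), 1)
        pi = pair_interaction_repulsive_only(si, sj, params)
        assert np.allclose(pi.f_dist, params.k_dist * np.array([-0.5, 0, 0]))
        assert np.allclose(pi.f_plane, 0)
        assert np.allclose(pi.t_tilt, 0)

    def test_same_object_rejected(self, params):
        si = make_surfel((0, 0, 0), (0, 0, 1), 2)
        sj = make_surfel((1, 0, 0), (0, 0, 1), 2)
        with pytest.raises(ValueError):
            pair_interaction_repulsive_only(si, sj, params)


class TestLocalMaxOffset:
    def test_ramp_maximum_at_far_end(self):
        vol = np.tile(np.arange(40, dtype=float), (40, 40, 1))  # increases with x
        img = Image3D(vol)
        off = local_max_offset(img, (20, 20, 20), (1, 0, 0), band=3.0)
        assert off == pytest.approx(3.0)
        off = local_max_offset(img, (20, 20, 20), (-1, 0, 0), band=3.0)
        assert off == pytest.approx(-3.0)

    def test_shell_seen_from_inside(self):
        img = sphere_shell((60, 60, 60), (29.5, 29.5, 29.5), 20, 2, 0.0, 0)
        # surfel 3 px inside the shell, looking outward
        off = local_max_offset(img, (46.5, 29.5, 29.5), (1, 0, 0), band=4.0)
        assert off == pytest.approx(3.0, abs=0.5)

    def test_flat_image_has_no_maximum(self, flat_image):
        assert local_max_offset(flat_image, (30, 30, 30), (0, 0, 1), 3.0) is None

    def test_fully_outside_returns_none(self, flat_image):
        assert local_max_offset(flat_image, (500, 500, 500), (0, 0, 1), 3.0) is None

    def test_plateau_tie_resolves_to_nearest(self):
        vol = np.zeros((40, 40, 40))
        vol[:, :, 18:22] = 1.0  # thick slab along x
        img = Image3D(vol)
        # already inside the plateau: nearest tied sample wins -> offset 0
        off = local_max_offset(img, (20, 20, 20), (1, 0, 0), band=3.0)
        assert off == 0.0


class TestImageForce:
    def test_on_maximum_both_forces_null(self):
        img = sphere_shell((60, 60, 60), (29.5, 29.5, 29.5), 20, 2, 0.0, 0)
        s = make_surfel((49.5, 29.5, 29.5), (1, 0, 0), 0)  # on the shell
        p = Params(d0=3, f_pressure=0.02)
        f = image_force(s, img, p)
        assert f.at_maximum
        assert np.allclose(f.f_total, 0)

    def test_maximum_ahead_sums_signed_norms(self):
        img = sphere_shell((60, 60, 60), (29.5, 29.5, 29.5), 20, 2, 0.0, 0)
        s = make_surfel((46.5, 29.5, 29.5), (1, 0, 0), 0)  # 3 px inside
        p = Params(d0=3, f_signal=0.02, f_pressure=0.01)
        f = image_force(s, img, p)
        assert not f.at_maximum
        assert np.allclose(f.f_total, (0.03, 0, 0), atol=1e-12)

    def test_flat_image_pressure_only(self, flat_image):
        s = make_surfel((30, 30, 30), (0, 0, 1), 0)
        p = Params(d0=3, f_pressure=-0.02)
        f = image_force(s, flat_image, p)
        assert not f.at_maximum
        assert np.allclose(f.f_total, (0, 0, -0.02))

    def test_signal_norm_is_constant_or_zero(self, rng):
        img = sphere_shell((60, 60, 60), (29.5, 29.5, 29.5), 20, 2, 0.5, 3)
        p = Params(d0=3, f_pressure=0.0)
        for _ in range(50):
            pos = rng.uniform(10, 50, 3)
            n = rng.standard_normal(3)
            s = make_surfel(pos, n, 0)
            f = image_force(s, img, p)
            mag = np.linalg.norm(f.f_total)
            assert mag == pytest.approx(0.0, abs=1e-12) or mag == pytest.approx(
                p.f_signal, rel=1e-9
            )


class TestBulkConsistency:
    def test_bulk_matches_scalar_for_aligned_pairs(self, params, rng):
        """Vectorised assembly reproduces the per-pair functions."""
        n = 40
        P = rng.uniform(0, 20, (n, 3))
        N = rng.standard_normal((n, 3))
        N /= np.linalg.norm(N, axis=1, keepdims=True)
        # force rough alignment so the anti-parallel gate stays out of play
        N[:, 2] = np.abs(N[:, 2]) + 1.0
        N /= np.linalg.norm(N, axis=1, keepdims=True)
        I = np.arange(n - 1)
        J = I + 1
        diff = P[J] - P[I]
        d = np.linalg.norm(diff, axis=1)
        u = diff / d[:, None]
        same = np.ones(len(I), dtype=bool)
        F, T = pair_forces_bulk(d, u, N[I], N[J], same, params)
        for k in range(len(I)):
            si = make_surfel(P[I[k]], N[I[k]], 0)
            sj = make_surfel(P[J[k]], N[J[k]], 0)
            pi = pair_interaction(si, sj, params)
            assert np.allclose(F[k], pi.force, atol=1e-10)
            assert np.allclose(T[k], pi.t_tilt, atol=1e-10)

    def test_antiparallel_same_object_pairs_repulsion_only(self, params):
        d0 = params.d0
        # face-to-face contact below d0: repulsion, no torque
        d = np.array([0.5 * d0])
        u = np.array([[1.0, 0, 0]])
        ni = np.array([[1.0, 0, 0]])
        nj = np.array([[-1.0, 0, 0]])
        F, T = pair_forces_bulk(d, u, ni, nj, np.array([True]), params)
        assert np.allclose(F[0], params.k_dist * np.array([-0.5, 0, 0]))
        assert np.allclose(T[0], 0)
        # and beyond d0 no bond forms across the contact
        F2, T2 = pair_forces_bulk(
            np.array([1.2 * d0]), u, ni, nj, np.array([True]), params
        )
        assert np.allclose(F2[0], 0)
        assert np.allclose(T2[0], 0)

    def test_bulk_image_force_matches_scalar(self, rng):
        img = sphere_shell((60, 60, 60), (29.5, 29.5, 29.5), 20, 2, 0.0, 0)
        p = Params(d0=3, f_pressure=0.015)
        P = rng.uniform(15, 45, (30, 3))
        N = rng.standard_normal((30, 3))
        N /= np.linalg.norm(N, axis=1, keepdims=True)
        F, atm = image_forces_bulk(img, P, N, p)
        for k in range(len(P)):
            f = image_force(make_surfel(P[k], N[k], 0), img, p)
            assert np.allclose(F[k], f.f_total, atol=1e-10)
            assert atm[k] == f.at_maximum
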