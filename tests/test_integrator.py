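import numpy as np
import pytest

from surfelseg import (
    Image3D,
    Params,
    PopulationCollapse,
    SurfelState,
    SurfelSystem,
    make_surfel,
    run,
    sphere_seed,
    step,
)

from conftest import hex_patch


def _no_adaptation(**kw):
    """Params with the density rules effectively disabled (huge balance period)."""
    kw.setdefault("d0", 3.0)
    kw.setdefault("rng_seed", 0)
    kw["balance_period"] = 10**9
    return Params(**kw)


class TestEulerUpdate:
    def test_constant_force_walks_at_d0_times_force(self, flat_image):
        """A constant total force of 0.01 with d0 = 15 moves 0.15 px/step,
        i.e. 100 steps for 15 px."""
        p = _no_adaptation(d0=15.0, f_pressure=0.01)
        s = make_surfel((30, 30, 10), (0, 0, 1), 0)
        sys_ = SurfelSystem.from_surfels([s], p)
        start = sys_.positions[0].copy()
        rep = step(sys_, flat_image)
        assert rep.max_displacement == pytest.approx(0.15, abs=1e-12)
        steps = 1
        while np.linalg.norm(sys_.positions[0] - start) < 15.0 - 1e-9:
            step(sys_, flat_image)
            steps += 1
        assert steps == 100

    def test_hex_patch_center_is_stationary(self, flat_image):
        # the central surfel sees a balanced neighbourhood and must not move;
        # rim surfels lack outer neighbours and may drift marginally
        p = _no_adaptation(f_pressure=0.0)
        sys_ = SurfelSystem.from_surfels(hex_patch(p.d0), p)
        # recentre the patch inside the volume
        sys_.positions += 30.0
        before = sys_.positions.copy()
        nrm = sys_.normals.copy()
        for _ in range(5):
            step(sys_, flat_image)
        assert np.abs(sys_.positions[0] - before[0]).max() < 1e-12
        assert np.abs(sys_.positions - before).max() < 0.02  # rim drift only
        assert np.abs(sys_.normals - nrm).max() < 1e-12  # flat: zero torques

    def test_close_pair_repels(self, flat_image):
        p = _no_adaptation(f_pressure=0.0)
        a = make_surfel((30, 30, 30), (0, 0, 1), 0)
        b = make_surfel((30 + 0.5 * p.d0, 30, 30), (0, 0, 1), 0)
        sys_ = SurfelSystem.from_surfels([a, b], p)
        d_before = np.linalg.norm(sys_.positions[1] - sys_.positions[0])
        step(sys_, flat_image)
        d_after = np.linalg.norm(sys_.positions[1] - sys_.positions[0])
        assert d_after > d_before

    def test_normals_stay_unit(self, flat_image, rng):
        p = _no_adaptation(f_pressure=0.005)
        surfels = [
            make_surfel(rng.uniform(20, 40, 3), rng.standard_normal(3), 0)
            for _ in range(30)
        ]
        sys_ = SurfelSystem.from_surfels(surfels, p)
        for _ in range(20):
            step(sys_, flat_image)
        dev = np.abs(np.linalg.norm(sys_.normals, axis=1) - 1).max()
        assert dev < 1e-9

    def test_locked_surfels_bitwise_stable_but_still_push(self, flat_image):
        p = _no_adaptation(f_pressure=0.0)
        a = make_surfel((30, 30, 30), (0, 0, 1), 0)
        b = make_surfel((30 + 0.5 * p.d0, 30, 30), (0, 0, 1), 0)
        sys_ = SurfelSystem.from_surfels([a, b], p)
        sys_.states[0] = SurfelState.LOCKED
        pos_locked = sys_.positions[0].copy()
        nrm_locked = sys_.normals[0].copy()
        b_before = sys_.positions[1].copy()
        for _ in range(3):
            step(sys_, flat_image)
        assert np.array_equal(sys_.positions[0], pos_locked)
        assert np.array_equal(sys_.normals[0], nrm_locked)
        assert np.linalg.norm(sys_.positions[1] - b_before) > 0  # still repelled


class TestConvergenceAndLocking:
    @staticmethod
    def _equilibrium_pair(p):
        a = make_surfel((30, 30, 30), (0, 0, 1), 0)
        b = make_surfel((30 + p.d0, 30, 30), (0, 0, 1), 0)
        return SurfelSystem.from_surfels([a, b], p)

    def test_still_pair_converges_and_locks(self, flat_image):
        p = _no_adaptation(f_pressure=0.0, conv_window=20)
        sys_ = self._equilibrium_pair(p)
        for _ in range(p.conv_window + 2):
            step(sys_, flat_image)
        assert sys_.n_locked == len(sys_)

    def test_drifting_neighbor_blocks_locking(self, flat_image):
        """A still surfel whose neighbour keeps moving may converge but must
        not lock."""
        from surfelseg import update_convergence

        p = _no_adaptation(f_pressure=0.0, conv_window=20)
        sys_ = self._equilibrium_pair(p)
        sys_.still_counters[:] = p.conv_window  # both due for a window check
        sys_._anchor_pos = sys_.positions.copy()
        sys_._anchor_nrm = sys_.normals.copy()
        sys_._anchor_pos[1] += (5.0, 0, 0)  # B moved 5 px over its window
        sys_._last_pairs = (np.array([0, 1]), np.array([1, 0]))
        update_convergence(sys_)
        assert sys_.states[0] == SurfelState.CONVERGED  # still, not locked
        assert sys_.states[1] == SurfelState.ACTIVE  # kept moving

    def test_all_neighbors_converged_triggers_lock(self):
        from surfelseg import update_convergence

        p = _no_adaptation(f_pressure=0.0, conv_window=20)
        sys_ = self._equilibrium_pair(p)
        sys_.still_counters[:] = p.conv_window
        sys_._anchor_pos = sys_.positions.copy()
        sys_._anchor_nrm = sys_.normals.copy()
        sys_._last_pairs = (np.array([0, 1]), np.array([1, 0]))
        update_convergence(sys_)
        assert sys_.n_locked == 2

    def test_locking_is_irreversible_within_run(self, flat_image):
        p = _no_adaptation(f_pressure=0.0, conv_window=10)
        sys_ = self._equilibrium_pair(p)
        for _ in range(p.conv_window + 2):
            step(sys_, flat_image)
        assert sys_.n_locked == 2
        # disturb the neighbourhood: locked surfels must not unlock
        sys_.add_surfels([make_surfel((30.6, 30.6, 30.0), (0, 0, 1), 0)])
        for _ in range(5):
            step(sys_, flat_image)
        assert sys_.n_locked >= 2

    def test_locked_set_monotone_within_run(self):
        from surfelseg import sphere_shell

        img = sphere_shell((60, 60, 60), (29.5, 29.5, 29.5), 15, 2, 0.0, 0)
        p = Params(d0=3, f_pressure=0.01, rng_seed=1)
        sys_ = SurfelSystem.from_surfels(sphere_seed((29.5, 29.5, 29.5), 6, 3, 0), p)
        locked_prev = 0
        for _ in range(900):
            rep = step(sys_, img)
            assert rep.n_locked >= locked_prev
            locked_prev = rep.n_locked
            if rep.n_locked == rep.n_total:
                break


class TestRun:
    def test_prelocked_system_returns_immediately(self, params, flat_image):
        sys_ = SurfelSystem.from_surfels(hex_patch(params.d0), params)
        sys_.positions += 30.0
        sys_.states[:] = SurfelState.LOCKED
        sys_, reports = run(sys_, flat_image, max_steps=100)
        assert reports == []
        assert sys_.step_count == 0

    def test_empty_system_rejected(self, params, flat_image):
        with pytest.raises(PopulationCollapse):
            run(SurfelSystem(params), flat_image)

    def test_pressure_only_sphere_growth_law(self, flat_image):
        """With no image signal a seed balloon inflates at close to
        d0 * f_pressure per step.  The rate runs somewhat below the
        free-particle value because the stretching membrane carries a bond
        tension that density adaptation relieves only with a lag."""
        p = Params(d0=3.0, f_pressure=0.01, rng_seed=0)
        c = np.array([30.0, 30, 30])
        sys_ = SurfelSystem.from_surfels(sphere_seed(c, 10, 3, 0), p)
        r0 = np.linalg.norm(sys_.positions - c, axis=1).mean()
        nsteps = 100
        for _ in range(nsteps):
            step(sys_, flat_image)
        r1 = np.linalg.norm(sys_.positions - c, axis=1).mean()
        rate = (r1 - r0) / nsteps
        ideal = p.d0 * p.f_pressure
        assert 0.6 * ideal < rate < 1.05 * ideal

    def test_resume_with_new_params_reactivates(self, flat_image):
        p = _no_adaptation(f_pressure=0.0, conv_window=10)
        sys_ = SurfelSystem.from_surfels(hex_patch(p.d0), p)
        sys_.positions += 30.0
        sys_, _ = run(sys_, flat_image, max_steps=100)
        assert sys_.n_locked == len(sys_)
        sys_.params = _no_adaptation(d0=2.0, f_pressure=0.0, conv_window=10)
        sys_, reports = run(sys_, flat_image, max_steps=5, reset=True)
        assert len(reports) == 5  # surfels active again, steps executed

    def test_report_counts_partition_population(self, flat_image):
        p = _no_adaptation(f_pressure=0.005)
        sys_ = SurfelSystem.from_surfels(sphere_seed((30, 30, 30), 6, 3, 0), p)
        rep = step(sys_, flat_image)
        assert rep.n_total == len(sys_)
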