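"""Particle simulator: steering, movement, trail dynamics, adaptation."""

import dataclasses

import numpy as np
import pytest

from plasmonet.arena import HeightField, RegionSite, make_arena
from plasmonet.sim import (
    SimConfig,
    SimError,
    adapt_population,
    diffuse_decay,
    effective_value,
    inoculate_full,
    motor_step,
    occupancy,
    project_stimuli,
    run_simulation,
    sense_and_steer,
)

NO_ADAPT = dict(growth_interval=0, shrink_interval=0)


def flat_arena(n=20, sites=()):
    return make_arena(np.ones((n, n), dtype=bool), sites)


def single_particle_state(arena, cfg, row, col, heading):
    """A state holding exactly one particle at (row, col)."""
    st = inoculate_full(arena, dataclasses.replace(cfg, init_density=1.0), seed=0)
    st.n = 1
    st.pos_r[0], st.pos_c[0] = float(row), float(col)
    st.cell_r[0], st.cell_c[0] = row, col
    st.heading[0] = heading
    st.occ[:] = -1
    st.occ[row, col] = 0
    st.trail[:] = 0.0
    return st


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(decay=1.0), dict(decay=-0.1), dict(sensor_angle=0),
         dict(rotation_angle=180), dict(sensor_offset=0.5),
         dict(diffusion_kernel=4), dict(init_density=0.0), dict(steps=-1)],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(SimError):
            SimConfig(**kwargs)


class TestInoculateFull:
    def test_density_one_fills_habitable(self):
        arena = flat_arena(10)
        st = inoculate_full(arena, SimConfig(init_density=1.0), seed=3)
        assert st.n == 100
        assert occupancy(st).all()
        assert np.all(st.trail == 0.0)

    def test_deterministic_given_seed(self):
        arena = flat_arena(30)
        a = inoculate_full(arena, SimConfig(init_density=0.5), seed=11)
        b = inoculate_full(arena, SimConfig(init_density=0.5), seed=11)
        assert a.n == b.n
        assert np.array_equal(a.cells(), b.cells())
        assert np.array_equal(a.headings(), b.headings())

    def test_population_near_binomial_mean(self):
        arena = flat_arena(100)
        st = inoculate_full(arena, SimConfig(init_density=0.5), seed=5)
        sd = np.sqrt(10000 * 0.25)
        assert abs(st.n - 5000) < 5 * sd

    def test_target_population_overrides_density(self):
        arena = flat_arena(100)
        st = inoculate_full(arena, SimConfig(target_population=2000), seed=1)
        assert abs(st.n - 2000) < 5 * np.sqrt(2000 * 0.8)

    def test_respects_mask(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        st = inoculate_full(make_arena(mask), SimConfig(init_density=1.0), seed=0)
        assert st.n == 50
        assert not occupancy(st)[5:].any()


class TestEffectiveValue:
    def test_flat_returns_trail(self):
        t = np.full((3, 3), 5.0)
        assert effective_value(t, None, (1, 1), 99.0) == 5.0

    def test_linear_height_penalty(self):
        t = np.full((3, 3), 5.0)
        hf = HeightField(np.ones((3, 3)))
        assert effective_value(t, hf, (1, 1), 2.0) == pytest.approx(3.0)

    def test_out_of_mask_is_minus_inf(self):
        t = np.zeros((3, 3))
        mask = np.ones((3, 3), bool)
        mask[0, 0] = False
        assert effective_value(t, None, (0, 0), 0.0, mask) == -np.inf
        assert effective_value(t, None, (-1, 0), 0.0) == -np.inf
        assert effective_value(t, None, (3, 0), 0.0) == -np.inf


class TestSenseAndSteer:
    """Three sensors at heading-SA, heading, heading+SA; the steering rule table."""

    def setup_method(self):
        self.arena = flat_arena(40)
        self.cfg = SimConfig(sensor_angle=45, rotation_angle=45, sensor_offset=9)
        self.rng = np.random.default_rng(0)

    def put(self, trail_vals, heading=90.0, pos=(20, 20)):
        """Place sensor values (left, front, right) for a given heading."""
        trail = np.zeros((40, 40))
        for v, da in zip(trail_vals, (-45, 0, 45)):
            a = np.deg2rad(heading + da)
            r = int(np.rint(pos[0] + 9 * np.sin(a)))
            c = int(np.rint(pos[1] + 9 * np.cos(a)))
            trail[r, c] = v
        return trail

    def test_all_equal_keeps_heading(self):
        trail = self.put((2, 2, 2))
        assert sense_and_steer(((20, 20), 90.0), trail, self.arena, self.cfg, self.rng) == 90.0

    def test_front_maximal_keeps_heading(self):
        trail = self.put((1, 9, 1))
        assert sense_and_steer(((20, 20), 90.0), trail, self.arena, self.cfg, self.rng) == 90.0

    def test_left_strictly_maximal_rotates_left(self):
        trail = self.put((9, 1, 2))
        assert sense_and_steer(((20, 20), 90.0), trail, self.arena, self.cfg, self.rng) == 45.0

    def test_right_strictly_maximal_rotates_right(self):
        trail = self.put((2, 1, 9))
        assert sense_and_steer(((20, 20), 90.0), trail, self.arena, self.cfg, self.rng) == 135.0

    def test_side_tie_above_front_turns_either_way(self):
        trail = self.put((7, 1, 7))
        seen = {
            sense_and_steer(((20, 20), 90.0), trail, self.arena, self.cfg,
                            np.random.default_rng(s))
            for s in range(40)
        }
        assert seen == {45.0, 135.0}


class TestMotorStep:
    def test_lone_mover_deposits_once(self):
        arena = flat_arena(20)
        cfg = SimConfig(**NO_ADAPT)
        st = single_particle_state(arena, cfg, 10, 10, heading=0.0)
        motor_step(st, arena, cfg)
        assert st.cells().tolist() == [[10, 11]]
        assert st.trail.sum() == pytest.approx(cfg.deposit)
        assert st.trail[10, 11] == pytest.approx(cfg.deposit)

    def test_blocked_by_occupied_cell_stays_and_rerandomizes(self):
        arena = flat_arena(20)
        cfg = SimConfig(**NO_ADAPT)
        st = single_particle_state(arena, cfg, 10, 10, heading=0.0)
        # a second particle occupies the destination, and each faces the other
        st.n = 2
        st.pos_r[1], st.pos_c[1] = 10.0, 11.0
        st.cell_r[1], st.cell_c[1] = 10, 11
        st.heading[1] = 180.0
        st.occ[10, 11] = 1
        before = st.cells().copy()
        motor_step(st, arena, cfg)
        assert np.array_equal(st.cells(), before)
        assert st.heading[0] != 0.0  # re-randomized
        assert st.trail.sum() == 0.0  # blocked movers deposit nothing

    def test_blocked_by_boundary_stays(self):
        arena = flat_arena(20)
        cfg = SimConfig(**NO_ADAPT)
        st = single_particle_state(arena, cfg, 0, 19, heading=0.0)  # facing +col
        motor_step(st, arena, cfg)
        assert st.cells().tolist() == [[0, 19]]

    def test_impassable_elevation_blocks(self):
        hf = HeightField(np.pad(np.ones((20, 1)) * 0.9, ((0, 0), (12, 7))))
        arena = make_arena(np.ones((20, 20), bool), [], hf)
        cfg = SimConfig(max_height=0.5, **NO_ADAPT)
        st = single_particle_state(arena, cfg, 10, 11, heading=0.0)
        motor_step(st, arena, cfg)
        assert st.cells().tolist() == [[10, 11]]


class TestProjectStimuli:
    def test_single_site_increment(self):
        t = np.zeros((5, 5))
        out = project_stimuli(t, [(2, 3)], 2.55)
        assert out[2, 3] == pytest.approx(2.55)
        assert out.sum() == pytest.approx(2.55)
        assert t.sum() == 0.0  # input untouched

    def test_empty_site_list_unchanged(self):
        t = np.ones((4, 4))
        assert np.array_equal(project_stimuli(t, [], 9.0), t)

    def test_shared_cell_accumulates(self):
        t = np.zeros((5, 5))
        out = project_stimuli(t, [(1, 1), (1, 1)], 2.55)
        assert out[1, 1] == pytest.approx(5.1)

    def test_site_off_grid_rejected(self):
        with pytest.raises(SimError):
            project_stimuli(np.zeros((4, 4)), [(5, 0)], 1.0)


class TestDiffuseDecay:
    def test_uniform_field_scales_by_decay(self):
        t = np.full((8, 8), 3.0)
        out = diffuse_decay(t, 3, 0.1)
        assert np.allclose(out, 2.7)

    def test_zero_field_stays_zero(self):
        assert not diffuse_decay(np.zeros((6, 6)), 3, 0.1).any()

    def test_even_kernel_rejected(self):
        with pytest.raises(SimError):
            diffuse_decay(np.zeros((4, 4)), 4, 0.1)

    def test_nonnegativity_preserved(self, rng):
        t = rng.random((30, 30)) * 50
        assert (diffuse_decay(t, 5, 0.3) >= 0).all()

    def test_toroidal_mass_balance(self, rng):
        """Wrap-around diffusion conserves mass: total after = (1-rho) * before."""
        for _ in range(10):
            t = rng.random((25, 31)) * 10
            t[rng.integers(25), rng.integers(31)] += 500.0  # spike
            out = diffuse_decay(t, 3, 0.1, toroidal=True)
            assert out.sum() == pytest.approx(0.9 * t.sum(), rel=1e-9)


class TestAdaptPopulation:
    def test_disabled_adaptation_conserves_count(self):
        arena = flat_arena(30)
        cfg = SimConfig(steps=50, init_density=0.4, **NO_ADAPT)
        st = run_simulation(arena, cfg, seed=9)
        assert st.n == inoculate_full(arena, cfg, seed=9).n
        assert len(set(st.population_curve)) == 1

    def test_lone_particle_removed_at_shrink_event(self):
        arena = flat_arena(20)
        cfg = SimConfig(shrink_window=5, shrink_min=1, shrink_interval=5,
                        growth_interval=0)
        st = single_particle_state(arena, cfg, 10, 10, heading=0.0)
        st.step = 5
        adapt_population(st, arena, cfg)
        assert st.n == 0

    def test_particle_with_neighbours_survives_shrink(self):
        arena = flat_arena(20)
        cfg = SimConfig(shrink_window=5, shrink_min=1, shrink_interval=5,
                        growth_interval=0)
        st = single_particle_state(arena, cfg, 10, 10, heading=0.0)
        st.n = 4
        for k, (r, c) in enumerate([(10, 11), (11, 10), (9, 10)], start=1):
            st.pos_r[k], st.pos_c[k] = float(r), float(c)
            st.cell_r[k], st.cell_c[k] = r, c
            st.occ[r, c] = k
        st.step = 5
        adapt_population(st, arena, cfg)
        assert st.n == 4

    def test_growth_spawns_into_free_neighbour(self):
        arena = flat_arena(20)
        cfg = SimConfig(growth_window=9, growth_min=1, growth_max=10,
                        growth_interval=5, shrink_interval=0)
        st = single_particle_state(arena, cfg, 10, 10, heading=0.0)
        st.step = 5
        adapt_population(st, arena, cfg)
        assert st.n == 2
        new = tuple(st.cells()[1])
        assert abs(new[0] - 10) + abs(new[1] - 10) == 1
        st.check_exclusion()


class TestRunSimulation:
    def test_zero_steps_returns_inoculated_state(self):
        arena = flat_arena(30)
        cfg = SimConfig(steps=0, init_density=0.5)
        st = run_simulation(arena, cfg, seed=4)
        ref = inoculate_full(arena, cfg, seed=4)
        assert np.array_equal(st.cells(), ref.cells())
        assert not st.trail.any()

    def test_bitwise_deterministic(self):
        arena = flat_arena(
            50, sites=[RegionSite(1, "a", 10, 10), RegionSite(2, "b", 40, 40)]
        )
        cfg = SimConfig(steps=60, init_density=0.3)
        a = run_simulation(arena, cfg, seed=21)
        b = run_simulation(arena, cfg, seed=21)
        assert a.n == b.n
        assert np.array_equal(a.cells(), b.cells())
        assert np.array_equal(a.positions(), b.positions())
        assert np.array_equal(a.trail, b.trail)

    def test_exclusion_and_nonnegativity_every_step(self):
        arena = flat_arena(
            100, sites=[RegionSite(1, "a", 20, 20), RegionSite(2, "b", 80, 80)]
        )
        seen = []

        def check(state):
            state.check_exclusion()
            assert (state.trail >= 0).all()
            seen.append(state.step)

        cfg = SimConfig(steps=40, init_density=0.25)
        run_simulation(arena, cfg, seed=2, check_exclusion=True,
                       snapshot_every=1, snapshot_cb=check)
        assert seen == list(range(1, 41))
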