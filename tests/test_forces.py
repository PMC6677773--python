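import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from flockhunt import SimulationConfig
from flockhunt.forces import (
    DegenerateGeometryError,
    assemble_predator_force,
    assemble_prey_force,
    coordination_prey,
    escape,
    hunting,
    pair_interaction,
    predator_friction,
    self_propulsion,
    wall_contact_force,
)
from flockhunt._kernel import MODE_CODES, compute_forces_alloc

coord = st.floats(min_value=-5, max_value=5, allow_nan=False)
vec2 = st.tuples(coord, coord)


class TestSelfPropulsion:
    def test_vanishes_at_terminal_speed(self):
        f = self_propulsion(1.0, (1.0, 0.0), (1.0, 0.0), beta=1.0, alpha=1.0)
        assert_allclose(f, [0.0, 0.0], atol=1e-12)

    def test_thrust_along_velocity(self):
        f = self_propulsion(2.0, (0.0, 2.0), (1.0, 0.0), beta=3.0, alpha=0.0)
        assert_allclose(f, [0.0, 6.0], atol=1e-12)

    def test_heading_fallback_at_rest(self):
        f = self_propulsion(1.0, (0.0, 0.0), (1.0, 0.0), beta=2.0, alpha=1.0)
        assert_allclose(f, [2.0, 0.0], atol=1e-12)


class TestCoordination:
    def test_zero_for_aligned_neighbourhood(self):
        assert_allclose(coordination_prey(10.0, 0.5, (1.0, 2.0), (1.0, 2.0)),
                        [0.0, 0.0], atol=1e-15)

    def test_hand_value(self):
        assert_allclose(coordination_prey(10.0, 0.5, (1.0, 0.0), (0.0, 0.0)),
                        [5.0, 0.0], atol=1e-12)

    def test_friction_hand_value(self):
        assert_allclose(predator_friction(1.0, 0.5, (2.0, 0.0)), [-1.0, 0.0],
                        atol=1e-12)

    @given(v=vec2, C_v=st.floats(0, 10), d=st.floats(0, 2))
    @settings(max_examples=60, deadline=None)
    def test_friction_opposes_motion(self, v, C_v, d):
        f = predator_friction(C_v, d, v)
        assert float(f @ np.asarray(v)) <= 1e-12


class TestPairInteraction:
    def test_attraction_toward_separated_neighbour(self):
        f = pair_interaction((0, 0), (1, 0), 0.5, 0.5, 2.0, "full_spring", cutoff=2.0)
        assert_allclose(f, [1.0, 0.0], atol=1e-12)

    def test_repulsion_on_overlap(self):
        f = pair_interaction((0, 0), (0.4, 0), 0.5, 0.5, 2.0, "full_spring", cutoff=2.0)
        assert_allclose(f, [-0.2, 0.0], atol=1e-12)

    def test_zero_at_exact_contact(self):
        f = pair_interaction((0, 0), (0.5, 0), 0.5, 0.5, 2.0, "full_spring", cutoff=2.0)
        assert_allclose(f, [0.0, 0.0], atol=1e-12)

    def test_literal_mode_has_no_repulsion(self):
        f = pair_interaction((0, 0), (0.4, 0), 0.5, 0.5, 2.0, "literal_attraction",
                             cutoff=2.0)
        assert_allclose(f, [0.0, 0.0])

    def test_contact_only_has_no_attraction(self):
        f = pair_interaction((0, 0), (1, 0), 0.5, 0.5, 2.0, "contact_only")
        assert_allclose(f, [0.0, 0.0])

    def test_cutoff_silences_far_pairs(self):
        f = pair_interaction((0, 0), (3, 0), 0.5, 0.5, 2.0, "full_spring", cutoff=2.0)
        assert_allclose(f, [0.0, 0.0])

    def test_coincident_positions_raise(self):
        with pytest.raises(DegenerateGeometryError):
            pair_interaction((0.5, 0.5), (0.5, 0.5), 0.1, 0.1, 1.0)

    @given(pi=vec2, pj=vec2,
           d=st.floats(0.05, 0.5), k=st.floats(0.1, 10),
           mode=st.sampled_from(["full_spring", "literal_attraction", "contact_only"]))
    @settings(max_examples=120, deadline=None)
    def test_newton_third_law(self, pi, pj, d, k, mode):
        if np.allclose(pi, pj):
            return
        fij = pair_interaction(pi, pj, d, d, k, mode, cutoff=3.0)
        fji = pair_interaction(pj, pi, d, d, k, mode, cutoff=3.0)
        assert_allclose(fij, -fji, atol=1e-10)


class TestEscapeAndHunting:
    def test_escape_points_away_from_predator(self):
        f = escape(1.0, 2.0, (0.5, 0.5), (0.5, 0.0))
        assert_allclose(f, [0.0, 2.0], atol=1e-12)

    def test_escape_zero_thrust(self):
        f = escape(1.0, 0.0, (0.3, 0.3), (0.0, 0.0))
        assert_allclose(f, [0.0, 0.0], atol=1e-15)

    @given(p=vec2, q=vec2, be=st.floats(0.1, 10))
    @settings(max_examples=60, deadline=None)
    def test_escape_magnitude_independent_of_distance(self, p, q, be):
        if np.allclose(p, q):
            return
        f = escape(1.5, be, p, q)
        assert np.hypot(*f) == pytest.approx(1.5 * be, rel=1e-12)

    def test_escape_coincident_falls_back_to_random_unit(self):
        f = escape(1.0, 2.0, (0.5, 0.5), (0.5, 0.5),
                   rng=np.random.default_rng(4))
        assert np.hypot(*f) == pytest.approx(2.0, rel=1e-12)

    def test_hunting_vanishes_at_terminal_speed(self):
        v = (np.sqrt(2.0), 0.0)  # |v|^2 = beta_h / gamma = 2
        f = hunting(16.0, 2.0, 1.0, v, (0, 0), (1, 0))
        assert_allclose(f, [0.0, 0.0], atol=1e-12)

    def test_hunting_hand_value(self):
        f = hunting(16.0, 1.0, 1.0, (0.0, 0.0), (0.0, 0.0), (1.0, 0.0))
        assert_allclose(f, [16.0, 0.0], atol=1e-12)

    def test_hunting_brakes_above_terminal_speed(self):
        f = hunting(16.0, 1.0, 1.0, (2.0, 0.0), (0.0, 0.0), (1.0, 0.0))
        assert f[0] < 0  # points away from the target

    def test_hunting_coincident_raises(self):
        with pytest.raises(DegenerateGeometryError):
            hunting(16.0, 1.0, 1.0, (0, 0), (0.5, 0.5), (0.5, 0.5))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _random_state(cfg, rng, n):
    margin = 3 * cfg.r
    pos = rng.uniform(margin, cfg.L - margin, size=(n, 2))
    vel = rng.normal(0, 1, size=(n, 2))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    head = np.column_stack([np.cos(theta), np.sin(theta)])
    xi = (rng.random(n) > 0.3).astype(np.uint8)
    agitated = (rng.random(n) > 0.5) & xi.astype(bool)
    return pos, vel, head, xi, agitated


class TestAssembly:
    def setup_method(self):
        self.cfg = SimulationConfig.from_groups(n=40, chi=604.0, tau_end=1.0)

    def _assemble_all(self, pos, vel, head, xi, agitated, ppos, escape_active):
        cfg = self.cfg
        n = len(pos)
        masses = np.full(n, cfg.m)
        diam = np.full(n, 2 * cfg.r)
        return [
            assemble_prey_force(i, pos, vel, head, xi, agitated, masses, diam,
                                ppos, 2 * cfg.R, cfg, escape_active)
            for i in range(n)
        ]

    def test_dead_prey_without_contacts_feels_nothing(self, rng):
        cfg = self.cfg
        pos = np.array([[0.5, 0.5], [0.9, 0.9]])
        vel = np.array([[1.0, 0.0], [0.0, 1.0]])
        head = vel.copy()
        xi = np.array([0, 1], dtype=np.uint8)
        agitated = np.zeros(2, dtype=bool)
        fb = assemble_prey_force(0, pos, vel, head, xi, agitated,
                                 np.full(2, cfg.m), np.full(2, 2 * cfg.r),
                                 np.array([0.1, 0.1]), 2 * cfg.R,
                                 cfg, escape_active=True)
        assert_allclose(fb.total, [0.0, 0.0], atol=1e-15)
        assert_allclose(fb.total, fb.f_pp, atol=0)

    def test_isolated_terminal_agent_is_force_free(self):
        cfg = self.cfg
        pos = np.array([[0.5, 0.5]])
        vel = np.array([[np.sqrt(cfg.beta / cfg.alpha), 0.0]])
        head = np.array([[1.0, 0.0]])
        fb = assemble_prey_force(0, pos, vel, head,
                                 np.ones(1, np.uint8), np.zeros(1, bool),
                                 np.full(1, cfg.m), np.full(1, 2 * cfg.r),
                                 np.array([0.1, 0.9]), 2 * cfg.R,
                                 cfg, escape_active=False)
        assert_allclose(fb.total, [0.0, 0.0], atol=1e-12)

    def test_gated_sum_structure(self, rng):
        """total must equal xi*(f_sp+f_c+f_e) + f_pp exactly."""
        pos, vel, head, xi, agitated = _random_state(self.cfg, rng, 25)
        ppos = np.array([0.5, 0.5])
        for i, fb in enumerate(self._assemble_all(pos, vel, head, xi, agitated,
                                                  ppos, True)):
            expected = xi[i] * (fb.f_sp + fb.f_c + fb.f_e) + fb.f_pp
            assert_allclose(fb.total, expected, atol=1e-15)
            if not xi[i]:
                assert_allclose(fb.total, fb.f_pp, atol=0)

    def test_predator_assembly_stationary_no_walls(self):
        cfg = self.cfg
        fb = assemble_predator_force(np.array([0.5, 0.5]), np.zeros(2),
                                     np.array([1.0, 0.0]), None, cfg,
                                     hunting_stage=False)
        assert_allclose(fb.total, fb.f_sp, atol=1e-15)
        assert_allclose(fb.f_h, [0.0, 0.0])

    def test_predator_hunting_adds_pursuit_term(self):
        cfg = self.cfg
        target = np.array([0.7, 0.5])
        fb = assemble_predator_force(np.array([0.5, 0.5]), np.zeros(2),
                                     np.array([0.0, 1.0]), target, cfg,
                                     hunting_stage=True)
        expected = hunting(cfg.M, cfg.beta_h, cfg.gamma, np.zeros(2),
                           np.array([0.5, 0.5]), target)
        assert_allclose(fb.f_h, expected, atol=1e-12)
        assert_allclose(fb.total, fb.f_sp + fb.f_c + fb.f_pp + fb.f_h, atol=1e-15)

    def test_prey_pair_forces_sum_to_zero(self, rng):
        """Newton's third law over a full random configuration."""
        cfg = self.cfg
        pos, vel, head, xi, agitated = _random_state(cfg, rng, 30)
        # place the predator and walls out of reach so only prey-prey acts
        ppos = np.array([cfg.L * 0.5, cfg.L * 0.5])
        n = len(pos)
        masses = np.full(n, cfg.m)
        diam = np.full(n, 2 * cfg.r)
        total = np.zeros(2)
        for i in range(n):
            fb = assemble_prey_force(i, pos, vel, head, xi, agitated, masses,
                                     diam, np.array([-10.0, -10.0]), 2 * cfg.R,
                                     cfg, False)
            total += fb.f_pp
        assert_allclose(total, [0.0, 0.0], atol=1e-10)

    @pytest.mark.parametrize("mode", ["full_spring", "literal_attraction",
                                      "contact_only"])
    def test_kernel_matches_reference_assembly(self, rng, mode):
        """The engine's numba kernel reproduces the pure-python force sums."""
        cfg = SimulationConfig.from_groups(n=40, chi=604.0, tau_end=1.0,
                                           interaction_mode=mode)
        pos, vel, head, xi, agitated = _random_state(cfg, rng, 40)
        # park some prey near walls and one on the predator to hit every branch
        pos[0] = [cfg.r * 1.2, 0.5]
        pos[1] = [0.5, cfg.L - cfg.r * 1.2]
        ppos = pos[2] + np.array([cfg.R * 0.8, 0.0])
        pvel = rng.normal(0, 1, 2)
        phead = np.array([0.0, 1.0])
        n = len(pos)
        masses = np.full(n, cfg.m)
        diam = np.full(n, 2 * cfg.r)
        present = np.ones(n, bool)
        target = 5
        F, Fp = compute_forces_alloc(
            pos, vel, head, xi, present, agitated, masses, diam,
            ppos, pvel, phead, 2 * cfg.R, cfg.M,
            cfg.beta, cfg.alpha, cfg.beta_e, cfg.beta_h, cfg.gamma, cfg.C_v,
            cfg.k_n, cfg.k_a, cfg.r_i, MODE_CODES[mode], cfg.dead_drag,
            cfg.coordination_live_only, True, True, target,
            cfg.L, cfg.r_w, 1e-9)
        for i in range(n):
            fb = assemble_prey_force(i, pos, vel, head, xi, agitated, masses,
                                     diam, ppos, 2 * cfg.R, cfg,
                                     escape_active=True)
            assert_allclose(F[i], fb.total, atol=1e-10, rtol=1e-10,
                            err_msg=f"prey {i}")
        fbp = assemble_predator_force(ppos, pvel, phead, pos[target], cfg,
                                      hunting_stage=True)
        assert_allclose(Fp, fbp.total, atol=1e-10, rtol=1e-10)

    def test_all_forces_finite_on_fuzzed_states(self, rng):
        cfg = self.cfg
        for _ in range(20):
            pos, vel, head, xi, agitated = _random_state(cfg, rng, 15)
            ppos = rng.uniform(0.1, 0.9, 2)
            for i in range(len(pos)):
                fb = assemble_prey_force(i, pos, vel, head, xi, agitated,
                                         np.full(15, cfg.m), np.full(15, 2 * cfg.r),
                                         ppos, 2 * cfg.R, cfg,
                                         escape_active=True)
                assert np.isfinite(fb.total).all()
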