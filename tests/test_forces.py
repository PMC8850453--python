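import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roamsim.forces import (AgentState, ModelParams, pair_repulsion,
                            propulsion_force, total_force, turning_force,
                            wall_force)
from roamsim.geometry import Arena, mirror_state, wall_frames


def _state(pos, vel, heading=None, chirality=0):
    return AgentState(position=np.array(pos, dtype=float),
                      velocity=np.array(vel, dtype=float),
                      heading=None if heading is None else np.array(heading, dtype=float),
                      chirality=chirality)


class TestModelParams:
    def test_defaults(self, params):
        assert (params.mu, params.v_d, params.r0) == (4.0, 1.5, 0.25)
        assert (params.A_P, params.B_p, params.eps) == (13.0, 0.85, 200.0)
        assert (params.A_w1, params.A_w2, params.B_w) == (15.0, 9.0, 0.4)

    @pytest.mark.parametrize("kw", [{"mu": 0}, {"v_d": -1}, {"gamma": -0.1},
                                    {"tp_ccw_fraction": 1.5}, {"wall_mode": "bogus"}])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_roundtrip(self, tmp_path, params):
        f = tmp_path / "params.json"
        params.replace(gamma=1.5, tp_enabled=True).save(f)
        loaded = ModelParams.load(f)
        assert loaded.gamma == 1.5 and loaded.tp_enabled


class TestPropulsion:
    def test_zero_at_desired_speed(self, params):
        s = _state([0, 0], [params.v_d, 0.0])
        np.testing.assert_allclose(propulsion_force(s, params), [0.0, 0.0])

    def test_from_rest(self, params):
        s = _state([0, 0], [0.0, 0.0], heading=[1.0, 0.0])
        np.testing.assert_allclose(propulsion_force(s, params), [6.0, 0.0])

    def test_braking_above_desired_speed(self, params):
        s = _state([0, 0], [2 * params.v_d, 0.0])
        f = propulsion_force(s, params)
        assert f[0] < 0 and f[1] == 0.0


class TestPairRepulsion:
    def test_amplitude_at_contact_long_branch(self, params):
        # r_ij just above 2 r0: magnitude -> A_P
        f = pair_repulsion([2 * params.r0 + 1e-12, 0.0], [0.0, 0.0], params)
        assert np.hypot(*f) == pytest.approx(13.0, rel=1e-9)

    def test_one_decay_length(self, params):
        f = pair_repulsion([2 * params.r0 + params.B_p, 0.0], [0.0, 0.0], params)
        assert np.hypot(*f) == pytest.approx(13.0 / np.e)
        assert np.hypot(*f) == pytest.approx(4.7824, abs=1e-4)

    def test_hertzian_half_overlap(self, params):
        f = pair_repulsion([params.r0, 0.0], [0.0, 0.0], params)
        assert np.hypot(*f) == pytest.approx(200.0 * 0.5 ** 1.5)
        assert np.hypot(*f) == pytest.approx(70.71, abs=0.01)

    def test_coincident_centres_raise(self, params):
        with pytest.raises(ValueError):
            pair_repulsion([1.0, 1.0], [1.0, 1.0], params)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        p = ModelParams()
        ri, rj = rng.uniform(-3, 3, size=(2, 2))
        if np.hypot(*(ri - rj)) < 1e-9:
            return
        np.testing.assert_allclose(pair_repulsion(ri, rj, p),
                                   -pair_repulsion(rj, ri, p), atol=1e-12)

    def test_contact_discontinuity_as_printed(self, params):
        # long-range branch gives A_P approaching contact from outside,
        # Hertzian branch gives 0 at contact: the jump is kept, not smoothed
        eps = 1e-9
        outside = pair_repulsion([2 * params.r0 + eps, 0.0], [0.0, 0.0], params)
        at = pair_repulsion([2 * params.r0, 0.0], [0.0, 0.0], params)
        assert np.hypot(*outside) == pytest.approx(13.0, rel=1e-6)
        assert np.hypot(*at) == pytest.approx(0.0, abs=1e-12)


class TestWallForce:
    def test_amplitude_at_contact(self, arena):
        # r_iw -> r0 from outside: the long-range branch tends to A_w1
        p = ModelParams(wall_mode="nearest_only")
        pos = [arena.half_width - p.r0 - 1e-12, 0.0]
        s = _state(pos, [0.0, 0.0], heading=[1.0, 0.0])
        f = wall_force(s, wall_frames(pos, arena), p)
        np.testing.assert_allclose(f, [-15.0, 0.0], atol=1e-8)

    def test_negligible_far_from_walls(self, arena):
        p = ModelParams(gamma=0.0)
        s = _state([0.0, 0.0], [1.0, 0.0])
        f = wall_force(s, wall_frames([0.0, 0.0], arena), p)
        assert np.hypot(*f) < 1e-6

    def test_damping_opposes_approach(self, arena):
        p = ModelParams(gamma=1.5, wall_mode="nearest_only")
        pos = [arena.half_width - p.r0 - 1e-12, 0.0]
        # moving toward the E wall at 1 m/s: v_n = v . n_hat = -1
        s = _state(pos, [1.0, 0.0])
        f = wall_force(s, wall_frames(pos, arena), p)
        np.testing.assert_allclose(f, [-(15.0 + 1.5), 0.0], atol=1e-8)

    def test_damping_range_cutoff(self, arena):
        p = ModelParams(gamma=2.0, wall_mode="nearest_only", damping_range=1.0)
        near = [arena.half_width - 1.0, 0.0]   # r_iw - r0 = 0.75 <= 1.0
        far = [arena.half_width - 1.5, 0.0]    # r_iw - r0 = 1.25 > 1.0
        sn = _state(near, [1.0, 0.0])
        sf = _state(far, [1.0, 0.0])
        fn = wall_force(sn, wall_frames(near, arena), p)
        ff = wall_force(sf, wall_frames(far, arena), p)
        p0 = p.replace(gamma=1e-12)
        fn0 = wall_force(sn, wall_frames(near, arena), p0)
        ff0 = wall_force(sf, wall_frames(far, arena), p0)
        # approaching the E wall: v_n = -1, so damping adds -gamma to the
        # (negative, outward) x force component
        assert fn[0] - fn0[0] == pytest.approx(-2.0, rel=1e-9)  # damping active
        assert ff[0] - ff0[0] == pytest.approx(0.0, abs=1e-12)  # beyond cutoff

    def test_literal_mode_unbounded_damping(self, arena):
        p = ModelParams(gamma=2.0, wall_mode="all_walls", damping_range=np.inf)
        pos = [0.0, 0.0]
        s = _state(pos, [1.0, 0.0])
        f = wall_force(s, wall_frames(pos, arena), p)
        # the literal form damps even mid-arena: E and W walls each contribute
        # -gamma*vx, i.e. a bulk drag of -2*gamma*v
        assert f[0] == pytest.approx(-2 * p.gamma * 1.0, abs=1e-3)

    def test_hertzian_inside_contact(self, arena):
        p = ModelParams(wall_mode="nearest_only")
        pos = [arena.half_width - p.r0 / 2, 0.0]
        s = _state(pos, [0.0, 0.0], heading=[1.0, 0.0])
        f = wall_force(s, wall_frames(pos, arena), p)
        assert f[0] == pytest.approx(-200.0 * 0.5 ** 1.5)


class TestTurningForce:
    def _tp(self, **kw):
        return ModelParams(tp_enabled=True, wall_mode="nearest_only", **kw)

    def test_parallel_walking_zero(self, arena):
        p = self._tp()
        pos = [arena.half_width - p.r0, 0.0]
        s = _state(pos, [0.0, 1.0], chirality=1)  # parallel to the E wall
        f = turning_force(s, wall_frames(pos, arena), p)
        np.testing.assert_allclose(f, [0.0, 0.0], atol=1e-12)

    def test_head_on_amplitude(self, arena):
        p = self._tp()
        pos = [arena.half_width - p.r0, 0.0]
        s = _state(pos, [1.0, 0.0], chirality=1)  # straight at the E wall
        f = turning_force(s, wall_frames(pos, arena), p)
        np.testing.assert_allclose(f, [0.0, 9.0], atol=1e-12)  # A_w2 along t_plus

    def test_moving_away_at_135_deg_zero(self, arena):
        # heading at 135 deg from the inward normal of the nearest (E) wall:
        # the agent moves away from it, so the turning force vanishes
        p = self._tp()
        pos = [arena.half_width - p.r0, 0.0]
        v = np.array([-1.0, 1.0]) / np.sqrt(2)  # 135 deg off the wall-ward +x
        s = _state(pos, v, chirality=1)
        f = turning_force(s, wall_frames(pos, arena), p)
        np.testing.assert_allclose(f, [0.0, 0.0], atol=1e-12)

    def test_chirality_flips_direction(self, arena):
        p = self._tp()
        pos = [arena.half_width - p.r0, 0.0]
        f_ccw = turning_force(_state(pos, [1.0, 0.0], chirality=1),
                              wall_frames(pos, arena), p)
        f_cw = turning_force(_state(pos, [1.0, 0.0], chirality=-1),
                             wall_frames(pos, arena), p)
        np.testing.assert_allclose(f_ccw, -f_cw)

    def test_requires_chirality(self, arena):
        p = self._tp()
        pos = [5.0, 0.0]
        with pytest.raises(ValueError):
            turning_force(_state(pos, [1.0, 0.0], chirality=0),
                          wall_frames(pos, arena), p)

    def test_magnitude_monotone_in_alpha(self, arena):
        p = self._tp()
        pos = [arena.half_width - p.r0, 0.0]
        frames = wall_frames(pos, arena)
        mags = []
        for a in np.radians([0, 20, 45, 70, 89.9]):
            v = np.array([np.cos(a), np.sin(a)])  # angle a from inward approach
            mags.append(np.hypot(*turning_force(_state(pos, v, chirality=1), frames, p)))
        assert mags[0] == pytest.approx(9.0)
        assert all(a > b for a, b in zip(mags, mags[1:]))


class TestTotalForce:
    def test_single_agent_center_propulsion_only(self, arena):
        p = ModelParams(gamma=1.5)
        s = _state([0.0, 0.0], [0.0, 0.0], heading=[1.0, 0.0])
        f = total_force(0, [s], arena, p)
        np.testing.assert_allclose(f, [6.0, 0.0], atol=1e-3)  # walls negligible at 3.35 m

    def test_pair_contribution_cancels(self, arena):
        p = ModelParams()
        s1 = _state([-1.0, 0.0], [0.0, 0.0], heading=[1.0, 0.0])
        s2 = _state([1.0, 0.0], [0.0, 0.0], heading=[-1.0, 0.0])
        from roamsim.forces import pair_repulsion
        f12 = pair_repulsion(s1.position, s2.position, p)
        f21 = pair_repulsion(s2.position, s1.position, p)
        np.testing.assert_allclose(f12 + f21, [0.0, 0.0], atol=1e-15)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_reflection_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        arena = Arena()
        p = ModelParams(gamma=1.2, tp_enabled=True)
        n = 4
        pos = rng.uniform(-1, 1, size=(n, 2)) * [4.5, 2.5]
        vel = rng.normal(scale=1.0, size=(n, 2))
        chi = rng.choice([-1, 1], size=n)
        heads = vel / np.hypot(vel[:, 0], vel[:, 1])[:, None]
        states = [_state(pos[i], vel[i], heading=heads[i], chirality=int(chi[i]))
                  for i in range(n)]
        mp, mv, mc = mirror_state(pos, vel, chi)
        mh = mv / np.hypot(mv[:, 0], mv[:, 1])[:, None]
        mstates = [_state(mp[i], mv[i], heading=mh[i], chirality=int(mc[i]))
                   for i in range(n)]
        for i in range(n):
            f = total_force(i, states, arena, p)
            fm = total_force(i, mstates, arena, p)
            np.testing.assert_allclose(fm, f * [1.0, -1.0], atol=1e-10)
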