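"""Environment layer: geometry, observations, rewards, dynamics, and I/O."""

import json

import numpy as np
import pytest
from hypothesis import given, strategies as st

from landmarkrl import (
    ActionCode,
    EnvState,
    Landmark,
    ObservationSpec,
    TerminalCause,
    Volume,
    apply_action,
    compute_reward,
    extract_plane_patch,
    observe,
    read_landmarks,
    read_volume,
    reset,
    step,
    write_landmarks,
    write_volume,
)
from landmarkrl.volume_env import ACTION_VECTORS


def brute_force_patch(volume, center, axis, spec):
    """Per-pixel reference sampler for the axis-normal patch."""
    ax = {"x": 0, "y": 1, "z": 2}[axis]
    in_plane = [a for a in range(3) if a != ax]
    half = spec.n // 2
    out = np.empty((spec.n, spec.n))
    for i in range(spec.n):
        for j in range(spec.n):
            idx = [0, 0, 0]
            idx[ax] = center[ax]
            idx[in_plane[0]] = center[in_plane[0]] - half + i
            idx[in_plane[1]] = center[in_plane[1]] - half + j
            if all(0 <= idx[a] < volume.shape[a] for a in range(3)):
                out[i, j] = volume.data[tuple(idx)]
            else:
                out[i, j] = spec.pad
    lo, hi = spec.window
    return (np.clip(out, lo, hi) - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Types and invariants
# ---------------------------------------------------------------------------

class TestTypes:
    def test_volume_rejects_bad_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            Volume(np.zeros((4, 4, 4)), spacing=(1.0, 0.0, 1.0))

    def test_volume_world_round_trip(self, small_volume):
        v = np.array([3, 7, 11])
        assert np.allclose(small_volume.voxel_from_world(small_volume.world_from_voxel(v)), v)

    def test_landmark_consistency_check(self, small_volume):
        lm = Landmark("bad", (2, 2, 2), (100.0, 100.0, 100.0))
        with pytest.raises(ValueError, match="inconsistent"):
            lm.validate_against(small_volume)

    def test_landmark_out_of_bounds(self, small_volume):
        lm = Landmark.from_voxel("x", (2, 2, 2), small_volume)
        Landmark("far", (99, 2, 2), lm.world_mm)
        with pytest.raises(ValueError, match="outside"):
            Landmark("far", (99, 2, 2), (0.0, 0.0, 0.0)).validate_against(small_volume)

    def test_observation_spec_validation(self):
        with pytest.raises(ValueError):
            ObservationSpec(n=2)
        with pytest.raises(ValueError):
            ObservationSpec(window=(1.0, 0.0))

    def test_action_set(self):
        assert len(ActionCode) == 7
        norms = np.linalg.norm(ACTION_VECTORS, axis=1)
        assert np.all(norms[:6] == 1) and norms[6] == 0


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

class TestPlanePatch:
    def test_constant_volume_gives_constant_patch(self):
        v = Volume(np.full((10, 10, 10), 0.4))
        spec = ObservationSpec(n=8, window=(0.0, 1.0))
        patch = extract_plane_patch(v, (5, 5, 5), "y", spec)
        assert np.allclose(patch, 0.4)

    def test_corner_center_has_padding_band(self):
        v = Volume(np.ones((10, 10, 10)))
        spec = ObservationSpec(n=8, window=(0.0, 1.0))
        patch = extract_plane_patch(v, (0, 0, 0), "z", spec)
        assert np.all(patch[: spec.n // 2, :] == 0.0)
        assert np.all(patch[:, : spec.n // 2] == 0.0)
        assert np.all(patch[spec.n // 2 :, spec.n // 2 :] == 1.0)

    @pytest.mark.parametrize("axis", ["x", "y", "z"])
    def test_matches_direct_slice_in_interior(self, small_volume, axis, obs_spec):
        center = (8, 8, 8)
        patch = extract_plane_patch(small_volume, center, axis, obs_spec)
        assert np.allclose(patch, brute_force_patch(small_volume, center, axis, obs_spec))

    def test_matches_brute_force_including_out_of_bounds(self, rng, obs_spec):
        v = Volume(rng.random((16, 16, 16)))
        for _ in range(50):
            center = tuple(int(c) for c in rng.integers(-12, 28, size=3))
            axis = "xyz"[rng.integers(3)]
            got = extract_plane_patch(v, center, axis, obs_spec)
            want = brute_force_patch(v, center, axis, obs_spec)
            assert np.allclose(got, want), (center, axis)

    def test_window_normalization_clips(self):
        v = Volume(np.full((8, 8, 8), 900.0))
        spec = ObservationSpec(n=4, window=(-200.0, 800.0))
        patch = extract_plane_patch(v, (4, 4, 4), "x", spec)
        assert np.allclose(patch, 1.0)


# ---------------------------------------------------------------------------
# Observation stacks
# ---------------------------------------------------------------------------

class TestObserve:
    def test_fresh_reset_replicates_frames(self, small_volume, obs_spec):
        env = reset(small_volume, (8, 8, 8), obs_spec)
        stack = observe(small_volume, env, obs_spec)
        assert stack.shape == (4, 3, 8, 8)
        for h in range(1, 4):
            assert np.array_equal(stack[h], stack[0])

    def test_stack_shape_at_paper_scale(self, small_volume):
        spec = ObservationSpec(n=32, history=3)
        env = reset(small_volume, (8, 8, 8), spec)
        assert observe(small_volume, env, spec).shape == (4, 3, 32, 32)

    def test_history_shift_after_steps(self, small_volume, obs_spec):
        gt = Landmark.from_voxel("t", (14, 14, 14), small_volume)
        env = reset(small_volume, (8, 8, 8), obs_spec)
        prev = observe(small_volume, env, obs_spec)
        for action in [ActionCode.POS_X, ActionCode.POS_Y, ActionCode.NEG_Z]:
            stack, _, env = step(small_volume, env, action, 1, gt, obs_spec, reach_tol=0.0)
            for h in range(1, obs_spec.history + 1):
                assert np.array_equal(stack[h], prev[h - 1])
            prev = stack

    def test_returned_stack_is_by_value(self, small_volume, obs_spec):
        env = reset(small_volume, (8, 8, 8), obs_spec)
        stack = observe(small_volume, env, obs_spec)
        stack[:] = -1.0
        assert not np.array_equal(observe(small_volume, env, obs_spec), stack)


# ---------------------------------------------------------------------------
# Dynamics and rewards
# ---------------------------------------------------------------------------

class TestDynamics:
    @pytest.mark.parametrize(
        "p,action,rho,expected",
        [
            ((0, 0, 0), ActionCode.POS_X, 3, (3, 0, 0)),
            ((5, 5, 5), ActionCode.STAY, 3, (5, 5, 5)),
            ((2, 3, 4), ActionCode.NEG_Z, 1, (2, 3, 3)),
        ],
    )
    def test_apply_action(self, p, action, rho, expected):
        assert tuple(apply_action(p, action, rho)) == expected

    def test_directional_moves_are_exactly_rho(self):
        for action in list(ActionCode)[:6]:
            d = np.linalg.norm(apply_action((5, 5, 5), action, 3) - np.array([5, 5, 5]))
            assert d == 3.0

    @pytest.mark.parametrize(
        "p_i,p_next,gt,expected",
        [
            ((0, 0, 0), (3, 0, 0), (10, 0, 0), 51.0),
            ((4, 4, 4), (4, 4, 4), (9, 1, 2), 0.0),
            ((3, 0, 0), (0, 0, 0), (10, 0, 0), -51.0),
        ],
    )
    def test_squared_reward_examples(self, p_i, p_next, gt, expected):
        assert compute_reward(p_i, p_next, gt) == expected

    def test_plain_reward(self):
        assert compute_reward((0, 0, 0), (3, 0, 0), (10, 0, 0), metric="plain") == 3.0

    @given(
        ps=st.lists(
            st.tuples(*[st.integers(-30, 30)] * 3), min_size=2, max_size=12
        ),
        gt=st.tuples(*[st.integers(-30, 30)] * 3),
    )
    def test_telescoping_sum(self, ps, gt):
        """Per-step rewards sum exactly to d^2(p_0) - d^2(p_T)."""
        total = sum(compute_reward(ps[i], ps[i + 1], gt) for i in range(len(ps) - 1))
        d2 = lambda p: float(np.sum((np.array(p) - np.array(gt)) ** 2))
        assert total == d2(ps[0]) - d2(ps[-1])

    @given(
        p=st.tuples(*[st.integers(-20, 20)] * 3),
        q=st.tuples(*[st.integers(-20, 20)] * 3),
        gt=st.tuples(*[st.integers(-20, 20)] * 3),
        shift=st.tuples(*[st.integers(-50, 50)] * 3),
        perm=st.permutations([0, 1, 2]),
    )
    def test_reward_invariances(self, p, q, gt, shift, perm):
        """Reward is invariant to global translation and axis permutation."""
        r = compute_reward(p, q, gt)
        t = lambda v: tuple(np.array(v) + np.array(shift))
        assert compute_reward(t(p), t(q), t(gt)) == r
        pi = lambda v: tuple(np.array(v)[list(perm)])
        assert compute_reward(pi(p), pi(q), pi(gt)) == r


class TestStep:
    def make(self, small_volume):
        return Landmark.from_voxel("t", (8, 8, 8), small_volume)

    def test_reach_termination(self, small_volume, obs_spec):
        gt = self.make(small_volume)
        env = reset(small_volume, (10, 8, 8), obs_spec)
        _, r, env = step(small_volume, env, ActionCode.NEG_X, 3, gt, obs_spec, reach_tol=3.0)
        assert env.terminal_cause == TerminalCause.REACHED_TARGET
        assert r == 4.0 - 1.0  # d^2 2^2 -> 1^2

    def test_out_of_bounds_termination(self, small_volume, obs_spec):
        gt = self.make(small_volume)
        env = reset(small_volume, (0, 8, 8), obs_spec)
        _, _, env = step(small_volume, env, ActionCode.NEG_X, 1, gt, obs_spec)
        assert env.terminal_cause == TerminalCause.OUT_OF_BOUNDS
        assert env.position == (-1, 8, 8)

    def test_max_steps_termination(self, small_volume, obs_spec):
        gt = self.make(small_volume)
        env = reset(small_volume, (2, 2, 2), obs_spec)
        for i in range(5):
            _, _, env = step(
                small_volume, env, ActionCode.STAY, 1, gt, obs_spec, max_steps=5, reach_tol=0.5
            )
        assert env.terminal_cause == TerminalCause.MAX_STEPS
        assert env.step_count == 5

    def test_stepping_terminal_env_raises(self, small_volume, obs_spec):
        gt = self.make(small_volume)
        env = reset(small_volume, (0, 8, 8), obs_spec)
        _, _, env = step(small_volume, env, ActionCode.NEG_X, 1, gt, obs_spec)
        with pytest.raises(RuntimeError, match="terminal"):
            step(small_volume, env, ActionCode.POS_X, 1, gt, obs_spec)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestVolumeIO:
    def test_nifti_round_trip(self, rng, tmp_path):
        v = Volume(rng.random((4, 5, 6)).astype(np.float32), spacing=(0.5, 0.6, 0.7), origin=(1, 2, 3))
        path = tmp_path / "vol.nii.gz"
        write_volume(v, path)
        back = read_volume(path)
        assert np.allclose(back.data, v.data)
        assert np.allclose(back.spacing, v.spacing)
        assert np.allclose(back.origin, v.origin)

    def test_metaimage_round_trip_spacing(self, rng, tmp_path):
        v = Volume(rng.random((4, 5, 6)).astype(np.float32), spacing=(0.33, 0.33, 0.33))
        path = tmp_path / "vol.mhd"
        write_volume(v, path)
        back = read_volume(path)
        assert back.spacing == (0.33, 0.33, 0.33)
        assert np.allclose(back.data, v.data)

    def test_truncated_raw_payload_errors(self, rng, tmp_path):
        v = Volume(rng.random((8, 8, 8)).astype(np.float32))
        path = tmp_path / "vol.mhd"
        write_volume(v, path)
        raw = tmp_path / "vol.raw"
        raw.write_bytes(raw.read_bytes()[: raw.stat().st_size // 2])
        with pytest.raises(IOError):
            read_volume(path)

    def test_unsupported_format(self, tmp_path):
        p = tmp_path / "vol.dat"
        p.write_text("nope")
        with pytest.raises(IOError, match="format"):
            read_volume(p)


class TestLandmarkIO:
    def test_round_trip(self, small_volume, tmp_path):
        lm = Landmark.from_voxel("LCA_ostium", (3, 4, 5), small_volume)
        path = tmp_path / "lm.json"
        write_landmarks([lm], path)
        (back,) = read_landmarks(path, small_volume)
        assert back == lm

    def test_missing_key_is_parse_error(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(json.dumps([{"name": "a", "world_mm": [0, 0, 0]}]))
        with pytest.raises(ValueError, match="voxel"):
            read_landmarks(path)

    def test_out_of_bounds_landmark_rejected_with_volume(self, small_volume, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text(
            json.dumps([{"name": "a", "voxel": [99, 0, 0], "world_mm": [32.67, 2.0, 0.0]}])
        )
        with pytest.raises(ValueError, match="outside"):
            read_landmarks(path, small_volume)

    def test_malformed_json_reports_line(self, tmp_path):
        path = tmp_path / "lm.json"
        path.write_text('[{"name": "a", }]')
        with pytest.raises(ValueError, match="line"):
            read_landmarks(path)
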