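import numpy as np
import pytest

from motionaug.fixtures import ObjectSpec, SceneSpec, generate_sequence
from motionaug.motion import (
    EstimatorUnavailableError,
    FlowField,
    MotionMap,
    background_frame,
    background_subtract_fd,
    background_subtract_knn,
    collapse_layers,
    flow_field,
    flow_to_layers,
    frame_difference_abs,
    frame_difference_dir,
)
from motionaug.sequence_io import FrameSequence

from oracles import (
    background_frame_loop,
    block_match_loop,
    bs_fd_loop,
    collapse_loop,
    fd_abs_loop,
    fd_dir_loop,
    knn_loop,
    luma_loop,
)


def _single_pixel_seq(values):
    """(n,) channel-0 values -> an n x 1 x 1 x 3 sequence (other channels 0.5)."""
    frames = np.full((len(values), 1, 1, 3), 0.5)
    frames[:, 0, 0, 0] = values
    return FrameSequence(frames=frames)


def _static_seq(value=0.4, n=12, h=6, w=6):
    return FrameSequence(frames=np.full((n, h, w, 3), value))


class TestFrameDifferencing:
    def test_static_fd_abs_zero(self):
        m = frame_difference_abs(_static_seq(), t=5, dt=2, upsilon=15.0)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_static_fd_dir_half(self):
        m = frame_difference_dir(_static_seq(), t=5, dt=2, upsilon=15.0)
        np.testing.assert_array_equal(m.values, 0.5)

    def test_fd_abs_hand_case(self):
        seq = _single_pixel_seq([0.2, 0.5, 0.7])
        m = frame_difference_abs(seq, t=1, dt=1, upsilon=1.0)
        assert m.values[0, 0, 0] == pytest.approx(0.25, abs=1e-15)

    def test_fd_abs_truncates_at_one(self):
        seq = _single_pixel_seq([0.2, 0.5, 0.7])
        m = frame_difference_abs(seq, t=1, dt=1, upsilon=15.0)
        assert m.values[0, 0, 0] == 1.0

    def test_fd_dir_hand_cases(self):
        up = frame_difference_dir(_single_pixel_seq([0.2, 0.5, 0.7]), t=1, dt=1, upsilon=1.0)
        assert up.values[0, 0, 0] == pytest.approx(0.7, abs=1e-15)
        down = frame_difference_dir(_single_pixel_seq([0.9, 0.5, 0.1]), t=1, dt=1, upsilon=1.0)
        assert down.values[0, 0, 0] == pytest.approx(0.2, abs=1e-15)

    def test_strict_boundary_names_missing_index(self):
        seq = _static_seq(n=5)
        with pytest.raises(Exception, match="-1"):
            frame_difference_abs(seq, t=1, dt=2, boundary="strict")

    def test_upsilon_monotonicity_before_clipping(self, rng):
        """|value - resting level| never decreases as upsilon grows."""
        seq = FrameSequence(frames=rng.uniform(0, 1, (5, 6, 6, 3)))
        for fn, rest in [(frame_difference_abs, 0.0), (frame_difference_dir, 0.5)]:
            prev = None
            for upsilon in [0.5, 1.0, 2.0, 5.0, 15.0]:
                dev = np.abs(fn(seq, 2, 1, upsilon).values - rest)
                if prev is not None:
                    assert (dev >= prev - 1e-12).all()
                prev = dev


class TestBackgroundSubtraction:
    def test_background_of_identical_frames(self):
        seq = _static_seq(0.37)
        np.testing.assert_allclose(background_frame(seq, 8, n_b=3, dt_b=2), 0.37, atol=1e-15)

    def test_background_hand_mean(self):
        seq = _single_pixel_seq([0.2, 0.4, 0.8])
        fb = background_frame(seq, t=2, n_b=2, dt_b=1)
        assert fb[0, 0, 0] == pytest.approx(0.3, abs=1e-15)

    def test_background_single_frame_is_that_frame(self, rng):
        seq = FrameSequence(frames=rng.uniform(0, 1, (4, 3, 3, 3)))
        np.testing.assert_array_equal(background_frame(seq, 3, n_b=1, dt_b=2), seq.frames[1])

    def test_bs_fd_static_half(self):
        m = background_subtract_fd(_static_seq(), t=8, n_b=4, dt_b=1, upsilon=15.0)
        np.testing.assert_array_equal(m.values, 0.5)

    def test_bs_fd_hand_case(self):
        seq = _single_pixel_seq([0.2, 0.4, 0.8])
        m = background_subtract_fd(seq, t=2, n_b=2, dt_b=1, upsilon=1.0)
        assert m.values[0, 0, 0] == pytest.approx(0.75, abs=1e-15)

    def test_bs_fd_truncates_at_one(self):
        seq = _single_pixel_seq([0.25, 0.25, 0.75])
        m = background_subtract_fd(seq, t=2, n_b=2, dt_b=1, upsilon=15.0)
        assert m.values[0, 0, 0] == 1.0

    def test_strict_reports_available_history(self):
        seq = _static_seq(n=5)
        with pytest.raises(ValueError, match="only 2 available"):
            background_frame(seq, t=2, n_b=5, dt_b=1, boundary="strict")


class TestKNN:
    def test_static_mask_zero(self):
        m = background_subtract_knn(_static_seq(n=60), t=55)
        np.testing.assert_array_equal(m.values, 0.0)

    def test_jumping_pixel_flagged(self):
        frames = np.zeros((10, 3, 3, 3))
        frames[-1, 1, 1, :] = 1.0
        m = background_subtract_knn(FrameSequence(frames=frames), t=9, history=9, k=3, dist_threshold=0.1)
        assert m.values[1, 1] == 1.0
        assert m.values.sum() == 1.0

    def test_output_binary(self, rng):
        seq = FrameSequence(frames=rng.uniform(0, 1, (20, 5, 5, 3)))
        m = background_subtract_knn(seq, t=19, history=10)
        assert set(np.unique(m.values)) <= {0.0, 1.0}

    def test_strict_insufficient_history_errors(self):
        with pytest.raises(ValueError, match="only 3 available"):
            background_subtract_knn(_static_seq(n=10), t=3, history=50, boundary="strict")


class TestFlow:
    def test_static_pair_zero_flow(self):
        fl = flow_field(_static_seq(n=4), t=1, dt=1)
        np.testing.assert_array_equal(fl.vx, 0.0)
        np.testing.assert_array_equal(fl.vy, 0.0)

    def test_rigid_translation_recovered(self, rng):
        base = rng.uniform(0, 1, (32, 32))
        shifted = np.roll(base, 3, axis=1)  # 3 px rightward
        frames = np.stack([np.repeat(a[..., None], 3, axis=-1) for a in (base, shifted)])
        fl = flow_field(FrameSequence(frames=frames), t=0, dt=1, radius=4, grid_step=4)
        assert np.median(fl.vx) == 3.0
        assert np.median(fl.vy) == 0.0

    def test_magnitude_pythagorean(self):
        fl = FlowField(vx=np.full((2, 2), 3.0), vy=np.full((2, 2), 4.0))
        np.testing.assert_allclose(fl.r, 5.0)

    def test_theta_range_and_quadrant(self):
        fl = FlowField(vx=np.array([[1.0, -1.0]]), vy=np.array([[0.0, -1.0]]))
        assert fl.theta[0, 0] == 0.0
        assert 0 <= fl.theta[0, 1] < 2 * np.pi
        assert fl.theta[0, 1] == pytest.approx(5 * np.pi / 4)

    def test_unknown_estimator_raises_capability_error(self):
        with pytest.raises(EstimatorUnavailableError):
            flow_field(_static_seq(n=4), t=0, dt=1, estimator="deep_flow")


class TestFlowLayers:
    def test_zero_flow_magnitude_all_zero(self):
        fl = FlowField(vx=np.zeros((4, 4)), vy=np.zeros((4, 4)))
        m = flow_to_layers(fl, mode="magnitude1")
        np.testing.assert_array_equal(m.values, 0.0)
        assert m.n_layers == 1

    def test_r_equal_rmax_maps_to_one(self):
        fl = FlowField(vx=np.array([[3.0]]), vy=np.array([[4.0]]))
        m = flow_to_layers(fl, mode="magnitude1", r_max=5.0)
        assert m.values[0, 0] == 1.0

    def test_hsv3_zero_flow_is_black(self):
        fl = FlowField(vx=np.zeros((3, 3)), vy=np.zeros((3, 3)))
        m = flow_to_layers(fl, mode="hsv3")
        np.testing.assert_array_equal(m.values, 0.0)
        assert m.n_layers == 3


class TestCollapse:
    def test_hand_mean(self):
        m = MotionMap(values=np.array([[[0.2, 0.4, 0.6]]]), method="fd_a")
        assert collapse_layers(m).values[0, 0] == pytest.approx(0.4, abs=1e-15)

    def test_constant_unchanged_and_idempotent_through_replication(self, rng):
        vals = rng.uniform(0, 1, (4, 4))
        m3 = MotionMap(values=np.repeat(vals[..., None], 3, axis=-1), method="fd_a")
        np.testing.assert_allclose(collapse_layers(m3).values, vals, atol=1e-15)

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            collapse_layers(MotionMap(values=np.zeros((2, 2)), method="bs_knn"))


class TestOracleEquivalence:
    """Every motion operator equals an independent scalar loop on random input."""

    N_SEQUENCES = 25  # per-test; the acceptance suite runs the full 100

    def _random_seq(self, rng):
        return FrameSequence(frames=rng.uniform(0, 1, (7, 8, 8, 3)))

    def test_differencing_family_matches_loops(self, rng):
        for _ in range(self.N_SEQUENCES):
            seq = self._random_seq(rng)
            t, dt = int(rng.integers(0, 7)), int(rng.integers(1, 3))
            upsilon = float(rng.choice([0.5, 1.0, 15.0]))
            np.testing.assert_allclose(
                frame_difference_abs(seq, t, dt, upsilon).values,
                fd_abs_loop(seq.frames, t, dt, upsilon),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                frame_difference_dir(seq, t, dt, upsilon).values,
                fd_dir_loop(seq.frames, t, dt, upsilon),
                atol=1e-12,
            )
            n_b, dt_b = int(rng.integers(1, 4)), int(rng.integers(1, 3))
            np.testing.assert_allclose(
                background_frame(seq, t, n_b, dt_b),
                background_frame_loop(seq.frames, t, n_b, dt_b),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                background_subtract_fd(seq, t, n_b, dt_b, upsilon).values,
                bs_fd_loop(seq.frames, t, n_b, dt_b, upsilon),
                atol=1e-12,
            )

    def test_knn_matches_loop(self, rng):
        for _ in range(self.N_SEQUENCES):
            seq = self._random_seq(rng)
            t = int(rng.integers(2, 7))
            np.testing.assert_allclose(
                background_subtract_knn(seq, t, history=5, k=3, dist_threshold=0.3).values,
                knn_loop(seq.frames, t, history=5, k=3, dist_threshold=0.3),
                atol=1e-12,
            )

    def test_block_match_flow_matches_loop(self, rng):
        for _ in range(5):
            seq = self._random_seq(rng)
            fl = flow_field(seq, t=2, dt=1, radius=2, block_radius=2, grid_step=4)
            vx_ref, vy_ref = block_match_loop(
                luma_loop(seq.frames[2]), luma_loop(seq.frames[3]), radius=2, block_radius=2, grid_step=4
            )
            np.testing.assert_allclose(fl.vx, vx_ref, atol=1e-12)
            np.testing.assert_allclose(fl.vy, vy_ref, atol=1e-12)

    def test_collapse_matches_loop(self, rng):
        vals = rng.uniform(0, 1, (8, 8, 3))
        m = MotionMap(values=vals, method="fd_a")
        np.testing.assert_allclose(collapse_layers(m).values, collapse_loop(vals), atol=1e-12)


class TestSyntheticRecovery:
    def test_moving_square_recovered_from_fd_abs(self):
        """Thresholded, collapsed FD_a recovers the union of the three GT boxes."""
        from motionaug.evaluation import iou

        for seed in range(5):
            obj = ObjectSpec(size=(12, 12), colour=(0.7, 0.7, 0.7), position=(6, 24), trajectory=[(2, 0)] * 8)
            spec = SceneSpec(height=64, width=64, n_frames=9, noise_sd=0.02, objects=[obj], seed=seed)
            seq, anns = generate_sequence(spec)
            t, dt = 4, 1
            m = collapse_layers(frame_difference_abs(seq, t, dt, upsilon=1.0))
            ys, xs = np.nonzero(m.values > 0.1)
            detected = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
            corners = [anns[s][0].to_corners(64, 64) for s in (t - dt, t, t + dt)]
            union = (
                min(c[0] for c in corners),
                min(c[1] for c in corners),
                max(c[2] for c in corners),
                max(c[3] for c in corners),
            )
            assert iou(detected, union) >= 0.9


class TestMotionMapPersistence:
    def test_png_sidecar_roundtrip(self, rng, tmp_path):
        import imageio.v3 as iio
        import json

        m1 = MotionMap(values=rng.uniform(0, 1, (6, 6)), method="bs_knn", params={"k": 3})
        m1.save(tmp_path / "mask.png")
        back1 = iio.imread(tmp_path / "mask.png") / 65535.0
        np.testing.assert_allclose(back1, m1.values, atol=0.5 / 65535)

        m3 = MotionMap(values=rng.uniform(0, 1, (6, 6, 3)), method="fd_d", params={"dt": 1, "upsilon": 1.0})
        m3.save(tmp_path / "map.png")
        sidecar = json.loads((tmp_path / "map.json").read_text())
        assert sidecar["method"] == "fd_d" and sidecar["params"]["dt"] == 1
        back3 = iio.imread(tmp_path / "map.png") / 255.0
        np.testing.assert_allclose(back3, m3.values, atol=0.5 / 255)
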