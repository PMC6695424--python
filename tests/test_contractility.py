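"""Unit tests for the movement-index pipeline."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from twitchindex import (
    FormatError,
    FrameStack,
    InsufficientFrames,
    NoContractionDetected,
    ParameterError,
    VideoSimConfig,
    movement_index,
    read_stack,
    simulate_myotube_field,
    summarize_fields,
    write_stack,
)
from twitchindex.contractility import (
    differential_image,
    find_first_max_contraction,
    motion_trace,
    overlay_diffs,
    pair_frames,
    render_pseudocolor,
)


class TestStackIO:
    def test_roundtrip_is_bit_identical(self, tmp_path):
        stack, _ = simulate_myotube_field(VideoSimConfig(seed=1))
        path = tmp_path / "stack.tif"
        write_stack(stack, path)
        back = read_stack(path)
        assert np.array_equal(back.frames, stack.frames)
        assert back.fps == stack.fps
        assert back.origin == "file"

    def test_integer_container_normalized_by_bit_depth(self, tmp_path):
        import tifffile

        arr = np.array([np.full((4, 4), 65535, dtype=np.uint16),
                        np.zeros((4, 4), dtype=np.uint16)])
        path = tmp_path / "u16.tif"
        tifffile.imwrite(path, arr, photometric="minisblack")
        stack = read_stack(path, fps=14.4)
        assert stack.frames.max() == 1.0 and stack.frames.min() == 0.0

    def test_single_frame_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "single.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(FormatError):
            read_stack(path, fps=14.4)

    def test_missing_fps_rejected(self, tmp_path):
        import tifffile

        path = tmp_path / "nofps.tif"
        tifffile.imwrite(path, np.zeros((3, 8, 8), dtype=np.uint8),
                         photometric="minisblack")
        with pytest.raises(ParameterError):
            read_stack(path)


class TestMotionTrace:
    def test_static_stack_gives_zero_trace(self, static_stack):
        assert (motion_trace(static_stack) == 0).all()

    def test_hand_computed_value(self):
        frames = np.array([[[0.0, 0.0]], [[0.2, 0.4]]])
        trace = motion_trace(FrameStack(frames, fps=10.0))
        assert trace[0] == 0.0
        assert trace[1] == pytest.approx(0.3)  # (0.2 + 0.4) / 2


class TestFirstMaxContraction:
    def test_static_stack_raises(self, static_stack):
        with pytest.raises(NoContractionDetected):
            find_first_max_contraction(
                motion_trace(static_stack), fps=10.0, stim_freq_hz=1.0
            )

    def test_two_identical_maxima_earliest_wins(self):
        trace = np.zeros(40)
        trace[10] = 1.0
        trace[24] = 1.0
        assert find_first_max_contraction(trace, 14.4, 1.0) == 10

    def test_noiseless_synthetic_anchor_matches_truth(self):
        stack, truth = simulate_myotube_field(
            VideoSimConfig(seed=6, noise_sd=0.0)
        )
        first = find_first_max_contraction(motion_trace(stack), 14.4, 1.0)
        assert abs(first - int(np.argmax(truth.displacement_trace))) <= 1


class TestPairFrames:
    def test_protocol_arithmetic_at_camera_rate(self):
        pairing = pair_frames(0, fps=14.4, stim_freq_hz=1.0, window_s=3.0,
                              n_frames=72)
        assert pairing.pairs == [(0, 7), (14, 21), (29, 36)]

    def test_integer_rate_offsets(self):
        pairing = pair_frames(5, fps=10.0, stim_freq_hz=1.0, window_s=5.0,
                              n_frames=200)
        assert len(pairing.pairs) == 5
        assert all(r - c == 5 for c, r in pairing.pairs)

    def test_no_room_for_a_pair(self):
        with pytest.raises(InsufficientFrames):
            pair_frames(70, fps=14.4, stim_freq_hz=1.0, window_s=3.0,
                        n_frames=72)

    @given(
        fps=st.floats(4.0, 60.0),
        freq=st.floats(0.25, 2.0),
        start=st.integers(0, 50),
        window=st.floats(3.0, 5.0),
    )
    def test_pair_structure_invariants(self, fps, freq, start, window):
        """Every pair sits half a period after its contraction frame and
        inside the stack."""
        if fps <= 2 * freq or window * freq < 1.0:
            return
        n_frames = 300
        pairing = pair_frames(start, fps, freq, window, n_frames)
        half = round(np.floor(fps / (2 * freq) + 0.5))
        assert pairing.pairs
        for c, r in pairing.pairs:
            assert r - c == half
            assert 0 <= c < n_frames and r < n_frames


class TestDifferentialImage:
    def test_hand_computed_difference(self):
        frames = np.array(
            [[[0.10, 0.20], [0.30, 0.40]], [[0.10, 0.25], [0.30, 0.40]]]
        )
        stack = FrameStack(frames, fps=10.0)
        diff = differential_image(stack, (0, 1))
        assert np.allclose(diff, [[0.0, 0.05], [0.0, 0.0]])

    def test_additive_offset_cancels(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(0.1, 0.5, size=(2, 6, 6))
        stack = FrameStack(frames, fps=10.0)
        shifted = FrameStack(frames + 0.1, fps=10.0)
        assert np.allclose(
            differential_image(stack, (0, 1)),
            differential_image(shifted, (0, 1)),
        )

    def test_out_of_range_pair(self, static_stack):
        with pytest.raises(ParameterError):
            differential_image(static_stack, (0, 1000))


class TestOverlay:
    def test_single_diff_is_identity(self):
        diff = np.array([[0.1, 0.2]])
        assert np.array_equal(overlay_diffs([diff]), diff)

    def test_mean_of_two(self):
        a = np.array([[0.0, 0.2]])
        b = np.array([[0.4, 0.0]])
        assert np.allclose(overlay_diffs([a, b]), [[0.2, 0.1]])

    def test_max_mode(self):
        a = np.array([[0.0, 0.2]])
        b = np.array([[0.4, 0.0]])
        assert np.allclose(overlay_diffs([a, b], mode="max"), [[0.4, 0.2]])

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            overlay_diffs([])


class TestMovementIndex:
    def test_static_stack_scores_zero_and_is_flagged(self, static_stack):
        result = movement_index(static_stack)
        assert result.movement_index == 0.0
        assert result.non_contractile

    def test_amplitude_ordering(self):
        mis = []
        for amplitude in (1.0, 4.0):
            stack, _ = simulate_myotube_field(
                VideoSimConfig(seed=7, noise_sd=0.0, amplitude_px=amplitude)
            )
            mis.append(movement_index(stack).movement_index)
        assert mis[0] < mis[1]

    def test_mean_overlay_index_equals_mean_of_pair_indices(self):
        stack, _ = simulate_myotube_field(VideoSimConfig(seed=9))
        result = movement_index(stack)
        assert result.movement_index == pytest.approx(
            result.per_pair_indices.mean()
        )
        assert (result.overlay >= 0).all()


class TestSummarizeFields:
    def test_closed_form_mean_and_se(self):
        summary = summarize_fields([0.1, 0.2, 0.3])
        assert summary.mean == pytest.approx(0.2)
        assert summary.se == pytest.approx(0.1 / np.sqrt(3))

    def test_single_field_has_no_se(self):
        summary = summarize_fields([0.42])
        assert summary.mean == 0.42
        assert summary.se is None

    def test_identical_fields_have_zero_se(self):
        assert summarize_fields([0.2, 0.2, 0.2]).se == pytest.approx(
            0.0, abs=1e-15
        )

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            summarize_fields([])


class TestRenderPseudocolor:
    def test_zero_overlay_renders_uniform_floor(self, tmp_path):
        rgb = render_pseudocolor(np.zeros((8, 8)), tmp_path / "zero.png")
        assert (rgb == rgb[0, 0]).all()
        assert (tmp_path / "zero.png").exists()

    def test_output_dimensions_and_determinism(self, tmp_path):
        overlay = np.random.default_rng(1).uniform(size=(12, 9))
        a = render_pseudocolor(overlay, tmp_path / "a.png")
        b = render_pseudocolor(overlay, None)
        assert a.shape == (12, 9, 3)
        assert np.array_equal(a, b)
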