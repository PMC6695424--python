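"""Unit tests for the synthetic-data generators."""

import numpy as np
import pytest

from twitchindex import (
    GeometryError,
    ParameterError,
    VideoSimConfig,
    simulate_ct_table,
    simulate_marker_table,
    simulate_myotube_field,
    simulate_nuclei_field,
    simulate_secretion_panel,
    simulate_twitch_trace,
)
from twitchindex.simkit import default_panel_class_map

from _brute import label_components


class TestTwitchTrace:
    def test_length_and_boundary_values(self):
        s = simulate_twitch_trace(fps=14.4, stim_freq_hz=1.0, duration_s=5.0)
        assert len(s) == 72  # 14.4 fps x 5 s
        assert s[0] == 0.0
        assert s.max() == 1.0
        assert (s >= 0).all() and (s <= 1).all()

    def test_peak_frame_within_first_cycle(self):
        # peak at rise time 0.1 s -> frame round(0.1 * 14.4) = 1
        s = simulate_twitch_trace(14.4, 1.0, 5.0, twitch_rise_s=0.1,
                                  twitch_decay_s=0.3)
        assert int(np.argmax(s)) == 1

    def test_autocorrelation_peaks_at_one_period(self):
        # 1 Hz at 14.4 fps -> dominant lag round(14.4) = 14
        s = simulate_twitch_trace(14.4, 1.0, 10.0)
        x = s - s.mean()
        ac = np.correlate(x, x, mode="full")[len(s) - 1:]
        lag = 8 + int(np.argmax(ac[8:22]))
        assert lag == 14

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"duration_s": -1.0},
            {"duration_s": 0.0},
            {"twitch_rise_s": 0.0},
            {"twitch_rise_s": 0.8, "twitch_decay_s": 0.5},  # > one cycle
        ],
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ParameterError):
            simulate_twitch_trace(14.4, 1.0, **{"duration_s": 5.0, **kwargs})


class TestMyotubeField:
    def test_no_motion_no_noise_means_identical_frames(self):
        stack, _ = simulate_myotube_field(
            VideoSimConfig(amplitude_px=0.0, noise_sd=0.0, seed=0)
        )
        assert (stack.frames == stack.frames[0]).all()

    def test_seed_determinism(self):
        cfg = VideoSimConfig(seed=11)
        a, ta = simulate_myotube_field(cfg)
        b, tb = simulate_myotube_field(cfg)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(ta.displacement_trace, tb.displacement_trace)

    def test_larger_amplitude_moves_more_pixels(self):
        # brute-force pixel arithmetic on the two generated stacks
        def peak_diff(amplitude):
            stack, truth = simulate_myotube_field(
                VideoSimConfig(amplitude_px=amplitude, noise_sd=0.0, seed=4)
            )
            peak = int(np.argmax(truth.displacement_trace))
            return np.abs(
                stack.frames[peak].astype(float)
                - stack.frames[0].astype(float)
            ).mean()

        assert peak_diff(4.0) > peak_diff(1.0)

    def test_intensities_clipped_to_unit_interval(self):
        stack, _ = simulate_myotube_field(
            VideoSimConfig(noise_sd=0.2, baseline=0.9, seed=2)
        )
        assert stack.frames.min() >= 0.0 and stack.frames.max() <= 1.0

    def test_truth_trace_matches_frame_count_and_masks_cover_myotubes(self):
        stack, truth = simulate_myotube_field(VideoSimConfig(seed=3))
        assert len(truth.displacement_trace) == stack.n_frames
        assert truth.myotube_masks.shape[0] == 5
        assert all(m.any() for m in truth.myotube_masks)

    def test_overlarge_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            simulate_myotube_field(
                VideoSimConfig(amplitude_px=200.0, seed=0)
            )


class TestNucleiField:
    def test_fraction_zero_gives_empty_hna(self):
        field, truth = simulate_nuclei_field(100, 0.0, seed=1)
        assert not field.hna_mask.any()
        assert truth.human_indices.size == 0

    def test_fraction_one_marks_every_nucleus(self):
        field, _ = simulate_nuclei_field(100, 1.0, seed=1)
        assert len(label_components(field.hna_mask)) == 100

    def test_truth_subset_matches_component_count(self):
        # conservation: planted subset size == brute-force component count
        field, truth = simulate_nuclei_field(100, 0.15, seed=9)
        assert len(label_components(field.dapi_mask)) == 100
        assert len(label_components(field.hna_mask)) == len(
            truth.human_indices
        )

    def test_hna_components_sit_on_dapi_components(self):
        field, _ = simulate_nuclei_field(60, 0.3, seed=5)
        assert not (field.hna_mask & ~field.dapi_mask).any()

    def test_placement_failure_raises_geometry_error(self):
        with pytest.raises(GeometryError):
            simulate_nuclei_field(500, 0.1, shape=(64, 64), seed=0)


class TestMarkerTable:
    def test_determinism_and_shape(self):
        a = simulate_marker_table(seed=8)
        b = simulate_marker_table(seed=8)
        assert a.equals(b)
        assert len(a) == 250
        assert set(a["population"]) == {
            "satellite", "blood", "endothelial", "FAP", "other"
        }

    def test_empty_satellite_population(self):
        table = simulate_marker_table(
            n_cells={"satellite": 0, "blood": 10}, seed=0
        )
        assert (table["population"] == "blood").all()

    def test_intensities_positive(self):
        table = simulate_marker_table(seed=2)
        markers = [c for c in table.columns if c != "population"]
        assert (table[markers] > 0).all().all()


class TestCtTable:
    def test_fold_one_zero_noise_means_equal_ct(self):
        table, _ = simulate_ct_table(
            {("human", "IL6"): 1.0}, noise_sd_ct=0.0, seed=0
        )
        target = table[table["gene"] == "IL6"]
        assert target.groupby("condition")["ct_value"].nunique().eq(1).all()
        assert target["ct_value"].nunique() == 1

    def test_fold_four_zero_noise_shifts_two_cycles(self):
        table, _ = simulate_ct_table(
            {("human", "IL6"): 4.0}, noise_sd_ct=0.0, seed=0
        )
        target = table[table["gene"] == "IL6"]
        means = target.groupby("condition")["ct_value"].mean()
        assert means["control"] - means["EPS"] == pytest.approx(2.0)

    def test_replicate_count(self):
        table, _ = simulate_ct_table(n_reps=3, seed=1)
        counts = table.groupby(["gene", "condition"]).size()
        assert (counts == 3).all()

    def test_reference_gene_in_every_sample_block(self):
        table, _ = simulate_ct_table(seed=1)
        for (sample, species), block in table.groupby(["sample", "species"]):
            ref = "RPLP0" if species == "human" else "GAPDH"
            assert ref in set(block["gene"])

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ParameterError):
            simulate_ct_table({("human", "IL6"): 0.0})


class TestSecretionPanel:
    def test_default_template_composition(self):
        class_map = default_panel_class_map()
        panel, truth = simulate_secretion_panel(seed=0)
        assert truth.analyte_classes == class_map
        assert panel.panel_size == len(class_map)
        assert set(panel.data["condition"]) == {
            "EPS", "control", "mouse_only_media", "blank"
        }

    def test_not_detected_class_stays_below_lod(self):
        analytes = {f"A{i}": "not_detected" for i in range(5)}
        panel, _ = simulate_secretion_panel(class_map=analytes, seed=3)
        lod = panel.lod.loc[panel.data["analyte"]].to_numpy()
        assert (panel.data["concentration"].to_numpy() < lod).all()

    def test_determinism(self):
        a, _ = simulate_secretion_panel(seed=6)
        b, _ = simulate_secretion_panel(seed=6)
        assert a.data.equals(b.data)

    def test_invalid_class_rejected(self):
        with pytest.raises(ParameterError):
            simulate_secretion_panel(class_map={"IL-6": "mystery"}, seed=0)
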