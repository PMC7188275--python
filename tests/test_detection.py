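import numpy as np
import pytest

from tfopt.audio_io import SegmentAnnotation
from tfopt.detection import (
    CRITERION_GRID,
    THRESHOLD_GRID,
    DetectionConfig,
    _trigger_indices,
    balanced_error,
    best_template_per_syllable,
    detect_songs,
    enumerate_elements,
    grid_search,
    stream_detect,
)
from tfopt.preprocess import AmplitudeThreshold, Slice
from tfopt.template import Template


FS = 44100


def make_song(labels_per_slice, distances, template_vector_dim=4):
    """Build a toy slice stream whose distances to a unit template are given."""
    slices = []
    annotations = []
    current = None
    for i, lab in enumerate(labels_per_slice):
        start = 256 * i
        center = (start + 128) / FS
        if lab != "gap":
            if current is None or current[0] != lab or current[2] != i - 1:
                if current is not None:
                    annotations.append(current_to_ann(current))
                current = [lab, i, i]
            else:
                current[2] = i
        else:
            if current is not None:
                annotations.append(current_to_ann(current))
                current = None
        slices.append(
            Slice(
                spectrum=np.zeros(template_vector_dim),
                start_sample=start,
                center_time=center,
                amplitude=10.0,
                label=lab,
            )
        )
    if current is not None:
        annotations.append(current_to_ann(current))
    # encode requested distance in the first spectrum component
    for s, d in zip(slices, distances):
        s.spectrum = np.zeros(template_vector_dim)
        s.spectrum[0] = d
    from tfopt.preprocess import label_slices

    label_slices(slices, annotations)
    return slices, annotations


def current_to_ann(cur):
    lab, i0, i1 = cur
    return SegmentAnnotation(
        onset=(256 * i0) / FS,
        offset=(256 * (i1 + 1)) / FS,
        label=lab,
        segment_type="syllable",
    )


def unit_template(theta=1.0, dim=4):
    return Template(
        vector=np.zeros(dim), syllable="A", position=0, sigma=0.2, theta=theta
    )


class TestTriggerIndices:
    def test_single_long_run_yields_floor_division_triggers(self):
        m = np.array([True] * 7)
        assert _trigger_indices(m, 3) == [2, 5]
        assert _trigger_indices(m, 1) == list(range(7))

    def test_run_shorter_than_criterion_never_triggers(self):
        m = np.array([True, True, False, True, True])
        assert _trigger_indices(m, 3) == []

    def test_matches_brute_force_counter_oracle(self, rng):
        for _ in range(100):
            m = rng.random(40) < 0.5
            for c in CRITERION_GRID:
                run = 0
                expected = []
                for i, v in enumerate(m):
                    run = run + 1 if v else 0
                    if run >= c:
                        expected.append(i)
                        run = 0
                assert _trigger_indices(m, c) == expected


class TestStreamDetect:
    def test_single_matching_slice_in_distractor_is_false_positive(self):
        labels = ["B"] * 4 + ["gap"] * 2 + ["A"] * 4
        dists = [5, 0.5, 5, 5, 5, 5, 5, 5, 5, 5]
        slices, anns = make_song(labels, dists)
        events = stream_detect(
            slices, unit_template(), DetectionConfig(criterion=1),
            annotations=anns,
        )
        assert len(events) == 1
        assert events[0].element_label == "B"

    def test_two_matches_do_not_satisfy_criterion_three(self):
        labels = ["A"] * 6
        dists = [5, 0.5, 0.5, 5, 5, 5]
        slices, anns = make_song(labels, dists)
        events = stream_detect(
            slices, unit_template(), DetectionConfig(criterion=3),
            annotations=anns,
        )
        assert events == []

    def test_trigger_counts_shrink_with_criterion(self, rng):
        # raising the criterion can only reduce the number of triggers
        # (floor(L/c) per maximal run is non-increasing in c); on songs
        # whose matching runs never span an element boundary, the detected
        # element sets are nested too
        for _ in range(50):
            m = rng.random(60) < 0.5
            counts = [len(_trigger_indices(m, c)) for c in CRITERION_GRID]
            assert (np.diff(counts) <= 0).all()
        for _ in range(20):
            # one long element: every run stays inside it
            labels = ["A"] * 40
            dists = rng.uniform(0, 2, size=40).tolist()
            slices, anns = make_song(labels, dists)
            prev = None
            for c in CRITERION_GRID:
                events = stream_detect(
                    slices, unit_template(), DetectionConfig(criterion=c),
                    annotations=anns,
                )
                got = {e.element_index for e in events}
                if prev is not None:
                    assert got <= prev
                prev = got

    def test_amplitude_gate_blocks_matches(self):
        labels = ["A"] * 4
        dists = [0.1] * 4
        slices, anns = make_song(labels, dists)
        for s in slices:
            s.amplitude = 0.5
        events = stream_detect(
            slices,
            unit_template(),
            DetectionConfig(
                criterion=1, amplitude_threshold=AmplitudeThreshold(1.0)
            ),
            annotations=anns,
        )
        assert events == []

    def test_one_event_per_element_even_with_many_runs(self):
        labels = ["A"] * 8
        dists = [0.5, 5, 0.5, 5, 0.5, 5, 0.5, 5]
        slices, anns = make_song(labels, dists)
        events = stream_detect(
            slices, unit_template(), DetectionConfig(criterion=1),
            annotations=anns,
        )
        assert len(events) == 1


class TestBalancedError:
    def test_hand_computed_report(self):
        labels = ["A"] * 3 + ["gap"] + ["B"] * 3 + ["gap"] + ["A"] * 3
        dists = [0.5] * 3 + [5] + [0.5, 5, 5] + [5] + [5] * 3
        slices, anns = make_song(labels, dists)
        elements = enumerate_elements(slices, anns)
        events = stream_detect(
            slices, unit_template(), DetectionConfig(criterion=1),
            elements=elements,
        )
        report = balanced_error(events, elements, "A")
        assert report.n_targets == 2
        assert report.false_negatives == 1  # second A undetected
        assert report.false_positives == 1  # B detected
        assert report.fn_ratio == 0.5 and report.fp_ratio == 0.5
        assert report.balanced_error == pytest.approx(50.0)

    def test_fp_ratio_may_exceed_one(self):
        labels = (["B"] * 2 + ["gap"]) * 4 + ["A"] * 2
        dists = [0.5] * len(labels)
        slices, anns = make_song(labels, dists)
        elements = enumerate_elements(slices, anns)
        events = stream_detect(
            slices, unit_template(), DetectionConfig(criterion=1),
            elements=elements,
        )
        report = balanced_error(events, elements, "A")
        assert report.n_targets == 1
        assert report.fp_ratio > 1.0

    def test_no_targets_rejected(self):
        labels = ["B"] * 3
        slices, anns = make_song(labels, [5] * 3)
        elements = enumerate_elements(slices, anns)
        with pytest.raises(ValueError, match="no target"):
            balanced_error([], elements, "A")


class TestGridSearch:
    def test_zero_threshold_fraction_gives_fifty_percent(self, small_songs, small_fit):
        _, test = small_songs
        tmpl = small_fit.optimized[0]
        _, _, table = grid_search(
            tmpl, test, "A", small_fit.amplitude_threshold
        )
        zero = table[table.threshold_fraction == 0]
        assert np.allclose(zero.fn_ratio, 1.0)
        assert np.allclose(zero.fp_ratio, 0.0)
        assert np.allclose(zero.balanced_error, 50.0)

    def test_grid_has_105_cells(self, small_songs, small_fit):
        _, test = small_songs
        _, _, table = grid_search(
            small_fit.optimized[0], test, "A", small_fit.amplitude_threshold
        )
        assert len(table) == len(THRESHOLD_GRID) * len(CRITERION_GRID) == 105

    def test_returned_minimum_matches_table_scan(self, small_songs, small_fit):
        _, test = small_songs
        cfg, err, table = grid_search(
            small_fit.optimized[0], test, "A", small_fit.amplitude_threshold
        )
        assert err == pytest.approx(table.balanced_error.min())
        row = table[
            (table.threshold_fraction == cfg.threshold_fraction)
            & (table.criterion == cfg.criterion)
        ]
        assert row.balanced_error.iloc[0] == pytest.approx(err)
        # tie-break: no strictly more stringent cell attains the same error
        ties = table[np.isclose(table.balanced_error, err)]
        assert cfg.threshold_fraction == ties.threshold_fraction.min()

    def test_match_sets_grow_with_threshold_fraction(self, small_songs, small_fit):
        _, test = small_songs
        _, _, table = grid_search(
            small_fit.optimized[0], test, "A", small_fit.amplitude_threshold
        )
        for crit in CRITERION_GRID:
            sub = table[table.criterion == crit].sort_values(
                "threshold_fraction"
            )
            assert (np.diff(sub.fn_ratio) <= 1e-12).all()


class TestBestTemplate:
    def test_single_template_returned(self, small_songs, small_fit):
        _, test = small_songs
        tmpl, cfg, err = best_template_per_syllable(
            [small_fit.optimized[0]], test, "A", small_fit.amplitude_threshold
        )
        assert tmpl is small_fit.optimized[0]

    def test_returned_error_is_min_over_positions(self, small_songs, small_fit):
        _, test = small_songs
        per_position = [
            grid_search(t, test, "A", small_fit.amplitude_threshold)[1]
            for t in small_fit.optimized
        ]
        _, _, err = best_template_per_syllable(
            small_fit.optimized, test, "A", small_fit.amplitude_threshold
        )
        assert err == pytest.approx(min(per_position))
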